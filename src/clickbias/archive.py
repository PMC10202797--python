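"""Reading, validating, filtering and summarizing headline-RCT archives.

An archive is a collection of independent randomized controlled trials
(experiments).  Each experiment tested several candidate headlines ("arms")
for the same news story; for every arm the platform recorded how many users
saw it (impressions) and how many clicked (clicks).  The click-through rate
(CTR) of an arm is clicks / impressions.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default physical column names (the Upworthy Research Archive dialect).
DEFAULT_COLUMNS = {
    "experiment_id": "clickability_test_id",
    "headline": "headline",
    "impressions": "impressions",
    "clicks": "clicks",
    "date": "created_at",
}


class ArchiveValidationError(ValueError):
    """A row in the archive violates a count or date invariant."""


class ArchiveConfigError(ValueError):
    """The column mapping does not resolve against the file header."""


@dataclass(frozen=True)
class ArmRecord:
    """One headline variation with its aggregated trial counts."""

    experiment_id: str
    headline_text: str
    impressions: int
    clicks: int
    created_at: _dt.date

    def __post_init__(self) -> None:
        if self.impressions < 0 or self.clicks < 0:
            raise ArchiveValidationError(
                f"negative counts for experiment {self.experiment_id!r}: "
                f"impressions={self.impressions}, clicks={self.clicks}"
            )
        if self.clicks > self.impressions:
            raise ArchiveValidationError(
                f"clicks ({self.clicks}) exceed impressions ({self.impressions}) "
                f"for experiment {self.experiment_id!r}"
            )


@dataclass
class Experiment:
    """An RCT: ≥1 arms testing headline variations of one news story."""

    experiment_id: str
    arms: list[ArmRecord]

    @property
    def date(self) -> _dt.date:
        """Experiment date: the earliest arm date."""
        return min(a.created_at for a in self.arms)

    @property
    def total_impressions(self) -> int:
        return sum(a.impressions for a in self.arms)

    @property
    def total_clicks(self) -> int:
        return sum(a.clicks for a in self.arms)


@dataclass
class Archive:
    """A collection of experiments plus the platform epoch.

    The epoch (date of the earliest experiment) anchors the platform-age
    covariate: the number of days each experiment ran after the platform's
    first experiment.
    """

    experiments: list[Experiment]
    n_removed_single_arm: int = 0
    n_merged_arms: int = 0
    n_dropped_zero_impressions: int = 0

    @property
    def platform_epoch(self) -> _dt.date:
        if not self.experiments:
            raise ValueError("empty archive has no epoch")
        return min(e.date for e in self.experiments)

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    @property
    def n_arms(self) -> int:
        return sum(len(e.arms) for e in self.experiments)

    def iter_arms(self):
        for exp in self.experiments:
            yield from exp.arms


@dataclass
class ArchiveSummary:
    n_experiments: int
    n_arms: int
    total_impressions: int
    total_clicks: int
    mean_ctr: float
    median_ctr: float
    arms_per_experiment_mean: float
    arms_per_experiment_median: float
    ccdf_points: list[tuple[float, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        d = dataclasses.asdict(self)
        d.pop("ccdf_points")
        return pd.DataFrame([d])

    def __str__(self) -> str:
        return (
            f"Archive summary: {self.n_experiments} experiments, "
            f"{self.n_arms} arms ({self.arms_per_experiment_mean:.2f} mean, "
            f"{self.arms_per_experiment_median:.0f} median arms/experiment); "
            f"{self.total_impressions:,} impressions, {self.total_clicks:,} clicks; "
            f"mean CTR {100 * self.mean_ctr:.2f}%, median CTR {100 * self.median_ctr:.2f}%"
        )


def ctr(arm: ArmRecord) -> float:
    """Click-through rate of one arm: clicks / impressions, in [0, 1]."""
    if arm.impressions < 1:
        raise ArchiveValidationError(
            f"CTR undefined for arm with 0 impressions (experiment {arm.experiment_id!r})"
        )
    return arm.clicks / arm.impressions


def platform_age_days(experiment: Experiment, epoch: _dt.date) -> int:
    """Whole days between the platform's first experiment and this one."""
    delta = (experiment.date - epoch).days
    if delta < 0:
        raise ArchiveValidationError(
            f"experiment {experiment.experiment_id!r} dated {experiment.date} "
            f"precedes the platform epoch {epoch}"
        )
    return delta


def _parse_date(value, row_label) -> _dt.date:
    ts = pd.to_datetime(value, errors="coerce", utc=True)
    if pd.isna(ts):
        raise ArchiveValidationError(f"unparseable date {value!r} at row {row_label}")
    return ts.date()


def read_archive(path, column_map: dict[str, str] | None = None) -> Archive:
    """Read a delimited archive file into an :class:`Archive`.

    Parameters
    ----------
    path
        CSV file (header row, UTF-8).
    column_map
        Mapping from logical names (``experiment_id``, ``headline``,
        ``impressions``, ``clicks``, ``date``) to physical column names.
        Defaults to the Upworthy Research Archive column names; partial
        mappings override individual entries.

    Arms with zero impressions are dropped with a warning rather than
    failing the archive: they carry no trial information.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(cols)
        if unknown:
            raise ArchiveConfigError(f"unknown logical column names: {sorted(unknown)}")
        cols.update(column_map)

    df = pd.read_csv(path, dtype={cols["experiment_id"]: str})
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ArchiveConfigError(
            f"mapped columns {missing} not present in file header {list(df.columns)}"
        )

    experiments: dict[str, list[ArmRecord]] = {}
    n_zero = 0
    for idx, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        impressions = int(rec[cols["impressions"]])
        clicks = int(rec[cols["clicks"]])
        if impressions == 0:
            if clicks > 0:
                raise ArchiveValidationError(
                    f"row {idx}: clicks={clicks} with zero impressions"
                )
            n_zero += 1
            continue
        arm = ArmRecord(
            experiment_id=str(rec[cols["experiment_id"]]),
            headline_text=str(rec[cols["headline"]]),
            impressions=impressions,
            clicks=clicks,
            created_at=_parse_date(rec[cols["date"]], idx),
        )
        experiments.setdefault(arm.experiment_id, []).append(arm)

    if n_zero:
        logger.warning("dropped %d arms with zero impressions", n_zero)
    return Archive(
        experiments=[Experiment(eid, arms) for eid, arms in experiments.items()],
        n_dropped_zero_impressions=n_zero,
    )


def write_archive(archive: Archive, path, column_map: dict[str, str] | None = None) -> None:
    """Write an archive back to CSV with the same (default) schema."""
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    rows = [
        {
            cols["experiment_id"]: a.experiment_id,
            cols["headline"]: a.headline_text,
            cols["impressions"]: a.impressions,
            cols["clicks"]: a.clicks,
            cols["date"]: a.created_at.isoformat(),
        }
        for a in archive.iter_arms()
    ]
    pd.DataFrame(rows, columns=list(cols.values())).to_csv(path, index=False)


def merge_duplicate_arms(experiment: Experiment) -> Experiment:
    """Collapse arms with identical headline text into one arm.

    Identity is exact string equality after trimming leading/trailing
    whitespace (no case folding: variant casing is a deliberate editorial
    treatment).  Clicks and impressions are summed; the earliest arm date
    is kept.  Experiment-level totals are conserved.
    """
    merged: dict[str, ArmRecord] = {}
    order: list[str] = []
    for arm in experiment.arms:
        key = arm.headline_text.strip()
        if key not in merged:
            merged[key] = arm
            order.append(key)
        else:
            prev = merged[key]
            merged[key] = ArmRecord(
                experiment_id=prev.experiment_id,
                headline_text=prev.headline_text,
                impressions=prev.impressions + arm.impressions,
                clicks=prev.clicks + arm.clicks,
                created_at=min(prev.created_at, arm.created_at),
            )
    return Experiment(experiment.experiment_id, [merged[k] for k in order])


def filter_archive(archive: Archive) -> Archive:
    """Apply the pre-analysis filtering rule.

    Duplicate-headline arms are merged first, then every experiment left
    with fewer than two (distinct) arms is removed.  Merging before
    removal guarantees the ≥2-distinct-arms invariant even when merging
    itself collapses an experiment to a single arm.  Idempotent.
    """
    kept: list[Experiment] = []
    n_removed = 0
    n_merged = 0
    for exp in archive.experiments:
        merged = merge_duplicate_arms(exp)
        n_merged += len(exp.arms) - len(merged.arms)
        if len(merged.arms) >= 2:
            kept.append(merged)
        else:
            n_removed += 1
    if not kept:
        warnings.warn("filtering removed every experiment", stacklevel=2)
    return Archive(
        experiments=kept,
        n_removed_single_arm=archive.n_removed_single_arm + n_removed,
        n_merged_arms=archive.n_merged_arms + n_merged,
        n_dropped_zero_impressions=archive.n_dropped_zero_impressions,
    )


def summarize_archive(archive: Archive) -> ArchiveSummary:
    """Summary statistics over arms and experiments, plus a CTR CCDF.

    The CCDF point at threshold t is the fraction of arms whose CTR is
    ≥ t, evaluated at every distinct observed CTR.
    """
    if not archive.experiments:
        raise ValueError("cannot summarize an empty archive")
    ctrs = np.array([ctr(a) for a in archive.iter_arms()])
    arms_per_exp = np.array([len(e.arms) for e in archive.experiments])
    thresholds = np.unique(ctrs)
    ccdf = [(float(t), float(np.mean(ctrs >= t))) for t in thresholds]
    return ArchiveSummary(
        n_experiments=archive.n_experiments,
        n_arms=archive.n_arms,
        total_impressions=sum(a.impressions for a in archive.iter_arms()),
        total_clicks=sum(a.clicks for a in archive.iter_arms()),
        mean_ctr=float(np.mean(ctrs)),
        median_ctr=float(np.median(ctrs)),
        arms_per_experiment_mean=float(np.mean(arms_per_exp)),
        arms_per_experiment_median=float(np.median(arms_per_exp)),
        ccdf_points=ccdf,
    )
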
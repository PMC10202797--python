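"""Generate a synthetic headline-RCT archive and summarize it.

The generator emulates a headline A/B testing platform: each experiment
tests several headline variations of one news story, with a baseline
click-through rate (CTR) near 1.4% and experiment-level heterogeneity.
"""

from clickbias import GeneratorConfig, generate_archive, summarize_archive

config = GeneratorConfig(seed=1, n_experiments=300)
archive, truth = generate_archive(config)

summary = summarize_archive(archive)
print(summary)
print(f"platform epoch: {archive.platform_epoch}")
print(f"true baseline CTR: {100 * 0.014:.1f}% (logistic of the true intercept)")
print(f"mean true per-headline CTR: {100 * truth.theta.mean():.2f}%")

# The summary's mean CTR is an unweighted average over headline arms; it
# sits slightly above the baseline because experiment-level random
# intercepts (SD 0.3 on the log-odds scale) spread CTRs asymmetrically.
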
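"""Mixed-model contrasts on a simulated band-energy table.

Simulates a 13-subject table with a known band profile and long/short
shifts, fits the hypercapnic two-term model (random subject intercept),
runs the likelihood-ratio tests and the 7 planned comparisons, and
prints estimates with Satterthwaite df, FDR-adjusted p and Cohen's d.
"""

from fnirspect.stats import (
    ModelSpec,
    effect_size_label,
    fit_lme,
    planned_contrasts,
    simulate_band_table,
    term_tests,
)

table = simulate_band_table(
    n_subjects=13,
    protocol="hypercapnic",
    band_means={"VLF": 3.0, "myogenic": 1.2, "respiratory": 0.4, "cardiac": 0.8},
    sds_effects={"VLF": -1.0, "myogenic": 0.4, "respiratory": 0.5, "cardiac": 0.9},
    subject_sd=0.5,
    seed=11,
)
model = fit_lme(table, ModelSpec("hypercapnic", "epsilon", "HbO", log10=False))
print(f"variance components: subject {model.tau2:.3f}, residual {model.sigma2:.3f}")

for term, t in term_tests(model).items():
    print(f"LRT {term:10s}: chi2({t['df']}) = {t['chi2']:.1f}, p = {t['p']:.2g}")

print("\nplanned comparisons (estimate, 95% CI, adjusted p, d):")
for c in planned_contrasts(model):
    print(f"  {c.label:28s} {c.estimate:7.3f} [{c.ci_low:6.3f}, {c.ci_high:6.3f}] "
          f"df={c.df:5.1f} p_adj={c.p_adjusted:8.2g} d={c.cohens_d:6.2f} "
          f"({effect_size_label(c.cohens_d)})")
print("\nThe large negative short-vs-long effect in VLF and the large positive one")
print("in cardiac recover the injected long-channel VLF / short-channel cardiac")
print("dominance; the smaller injected myogenic and respiratory shifts (0.4-0.5,")
print("about 1.5 SE at 13 subjects) are not reliably detected at this cohort size.")
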
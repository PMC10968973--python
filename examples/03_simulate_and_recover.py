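"""Generate a synthetic SEER-like cohort and recover its known parameters.

Builds a 10,000-patient cohort with a known under-45 location odds ratio
of 2.0 and sex-confounded location assignment, pushes it through the
exclusion filters, and checks that the univariable odds ratio estimator
recovers the injected truth.
"""

from sigreach import apply_exclusions, crosstab, odds_ratio_univariable
from sigreach.synthetic import GeneratorConfig, default_subsite_probs, generate

base = default_subsite_probs()


def with_visualizable_share(probs, share):
    vis = {c: p for c, p in probs.items() if c in ("C186", "C187", "C199", "C209")}
    col = {c: p for c, p in probs.items() if c not in vis}
    sv, sc = sum(vis.values()), sum(col.values())
    return {**{c: p / sv * share for c, p in vis.items()},
            **{c: p / sc * (1 - share) for c, p in col.items()}}


cfg = GeneratorConfig(
    n_patients=10_000,
    seed=7,
    confounding_log_odds={("sex", "male"): 0.4},
    subsite_probs_by_age={
        "under45": with_visualizable_share(base["under45"], 2 / 3),  # odds 2
        "45to49": with_visualizable_share(base["45to49"], 1 / 2),    # odds 1
        "50plus": with_visualizable_share(base["50plus"], 1 / 2),
    },
)
raw, truth = generate(cfg)
cohort, log = apply_exclusions(raw)
print(f"generated {len(raw)}, excluded {sum(log.counts.values())} "
      f"({dict(log.counts)})")

est = odds_ratio_univariable(crosstab(cohort, "age_group", "50plus"), "under45")
print(f"\ntrue under-45 reach OR: 2.00")
print(f"recovered:              {est.odds_ratio:.2f} "
      f"(95% CI {est.ci_low:.2f}-{est.ci_high:.2f})")
print("\nThe CI should cover 2.0: the estimator is consistent for the "
      "odds ratio injected through the subsite mixtures.")
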
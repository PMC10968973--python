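"""IPW-adjusted survival contrast between tumor-location groups.

Simulates a 50+/regional-stage stratum whose survival is exponential per
location group (closed-form truth known), estimates IPW-weighted
Kaplan-Meier curves adjusted for a sex-location confounder, and reports
the DRMST at 5 years with a bootstrap Z-test and 99% percentile CI.
"""

from sigreach.data_model import add_derived_columns
from sigreach.ipw_survival import bootstrap_inference, make_drmst_statistic
from sigreach.synthetic import GeneratorConfig, generate

VIS, COL = "VISUALIZABLE", "REQUIRES_COLONOSCOPY"

cfg = GeneratorConfig(
    n_patients=4_000,
    seed=11,
    age_group_mix={"under45": 0.0, "45to49": 0.0, "50plus": 1.0},
    stage_mix_by_reach={
        VIS: {"localized": 0.0, "regional": 1.0, "distant": 0.0},
        COL: {"localized": 0.0, "regional": 1.0, "distant": 0.0},
    },
    confounding_log_odds={("sex", "male"): 0.5},
)
cohort = add_derived_columns(generate(cfg)[0])

tau = 60.0
stat = make_drmst_statistic(tau, covariates=("sex",))
res = bootstrap_inference(cohort, stat, n_reps=500, seed=12, ci_level=0.99)

print(f"true DRMST at {tau:.0f} months:      {cfg.true_drmst('regional', tau):.2f}")
print(f"estimated DRMST (IPW, boot):  {res.value:.2f} months")
print(f"bootstrap SE:                 {res.se:.2f}")
print(f"Z = {res.z:.2f}, p = {res.p:.2e}")
print(f"99% percentile CI:            ({res.ci_low:.2f}, {res.ci_high:.2f})")
print("\nA positive DRMST means patients with sigmoidoscopy-visualizable "
      "tumors live longer (restricted to the horizon) than those with "
      "proximal tumors, after balancing the sex mix of the two groups.")
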
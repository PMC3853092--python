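"""Reproduce the published dose-regression table from its group means.

Fits linear and quadratic models of each neuromorphology feature against
x = log10(nocodazole ng/mL) (control -> 0) using the packaged six-dose
group means, applies the 5%-improvement model-selection rule, and prints
the selected equation plus the share of between-dose variance each model
captures.  A fit capturing > 90% is flagged successful.
"""

import numpy as np

from hcsneurons import fit_group_means, load_reference_group_means

DOSES = np.array([0.0, 10.0, 50.0, 100.0, 200.0, 1000.0])

ref = load_reference_group_means()
print(f"{'feature':<22}{'model':<11}{'equation':<34}{'var.expl.%':>10}  ok")
for _, row in ref.iterrows():
    means = row[[f"dose_{d:g}" for d in DOSES]].to_numpy(float)
    fit = fit_group_means(DOSES, means, anova_r2=row.anova_r2, feature_name=row.feature)
    print(
        f"{row.feature:<22}{fit.selected_model:<11}{fit.equation:<34}"
        f"{fit.variance_explained:>10.1f}  {'yes' if fit.successful else 'no'}"
    )
print(
    "\nsomaCount follows a quadratic arc in log-dose (rise to 50 ng/mL, then"
    "\ncollapse); the neurite features decline linearly -- the signature of"
    "\ndrug-induced neurite retraction."
)
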
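"""Small synthetic dose study: generate, extract, run the ANOVA chain.

Generates a 6-dose x 8-image series, extracts the 13-feature descriptor
from every frame, and runs the Bartlett-gated ANOVA + Tukey + log-dose
regression on each feature.  Expect the neurite features to show strong
negative dose trends (high ANOVA R^2) and a "successful" regression.
"""

import pandas as pd

from hcsneurons import DoseSeriesConfig, analyze_all_features, extract_nfd, generate_dose_series

records = generate_dose_series(DoseSeriesConfig(images_per_dose=8, seed=4))
table = pd.DataFrame(
    [extract_nfd(img).to_dict() | {"dose_ng_per_ml": dose} for img, _, dose in records]
)
reports = analyze_all_features(table)

print(f"{'feature':<22}{'ANOVA R2%':>9}{'welch':>7}{'pearson':>9}{'model':>11}{'ok':>4}")
for name, rep in reports.items():
    print(
        f"{name:<22}{rep.anova.r_squared:>9.1f}{str(rep.anova.used_welch):>7}"
        f"{rep.pearson_r:>9.2f}{rep.regression.selected_model:>11}"
        f"{'yes' if rep.regression.successful else 'no':>4}"
    )
print(
    "\nNegative Pearson r on neurite features = dose-dependent retraction;"
    "\nAvg_somaArea trends positive because clustered somata merge."
)
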
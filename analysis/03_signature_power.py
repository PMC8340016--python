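"""Can the pipeline detect a genuinely prognostic module?

Over replicated synthetic cohorts (latent hazard factor with beta = 1,
400 samples, a 10-gene module at unit loading/noise), the planted
signature is scored by PC1 -> median split -> log-rank, and the PC1
scores are compared with the latent factor itself. Reports detection
power at alpha = 0.05 and the distribution of |corr(PC1, f)|.

Writes results/signature_power.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from grpsig.stratification import pc1_scores
from grpsig.survival import outcome_association
from grpsig.synthetic import SyntheticConfig, make_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"
N_REPS = 200


def main() -> None:
    rows = []
    for rep in range(N_REPS):
        cfg = SyntheticConfig(
            n_genes=2000, n_samples=400, module_size=10,
            log_hazard_beta=1.0, seed=rep,
        )
        cohort, truth = make_cohort(cfg)
        module = set(truth["module_genes"])
        assoc = outcome_association(cohort, module)
        corr = abs(np.corrcoef(
            pc1_scores(cohort, module).values, truth["latent_factor"]
        )[0, 1])
        rows.append({"seed": rep, "p_value": assoc.p_value, "abs_corr": corr})
    df = pd.DataFrame(rows)
    ROOT.mkdir(exist_ok=True)
    df.to_csv(ROOT / "signature_power.tsv", sep="\t", index=False)
    power = (df.p_value < 0.05).mean()
    print(f"{N_REPS} replicates at beta=1, n=400, module=10, b/noise=1:")
    print(f"  power at alpha=0.05: {power:.3f}")
    print(
        f"  |corr(PC1, latent f)|: mean {df.abs_corr.mean():.3f}, "
        f"min {df.abs_corr.min():.3f}"
    )


if __name__ == "__main__":
    main()
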
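"""Generate the synthetic study bundle used by the downstream analyses.

Writes a complete input set — GO-like ontology, gene annotations, the
signature catalog fixtures (a planted prognostic module plus 32 decoys
mirroring the published prostate-cancer signature sizes), an expression
matrix with latent-factor survival structure, and clinical follow-up —
to results/bundle/, in the same plain-text formats the pipeline reads.
"""

from pathlib import Path

from grpsig.synthetic import SyntheticConfig, write_bundle

OUT = Path(__file__).resolve().parent.parent / "results" / "bundle"
SEED = 0


def main() -> None:
    cfg = SyntheticConfig(seed=SEED)  # defaults: 2000 genes x 498 samples
    truth = write_bundle(OUT, cfg)
    print(f"bundle written to {OUT}")
    print(
        f"  {cfg.n_genes} genes x {cfg.n_samples} samples; "
        f"module genes {truth['module_genes']}"
    )
    print(
        f"  survival: baseline hazard {cfg.hazard_baseline}/day, "
        f"beta {cfg.log_hazard_beta}, censoring {cfg.censoring_rate}/day, "
        f"cutoff {cfg.admin_cutoff_days:.0f} days"
    )


if __name__ == "__main__":
    main()
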
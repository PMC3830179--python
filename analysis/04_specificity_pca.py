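#!/usr/bin/env python
"""Specificity screen: one shared PCA identification model for both APIs.

Fits the PCA library on all 108 calibration spectra (both blend series) and
challenges it with the proof set — excipient placebo, the 10%-DHA degraded
blend, pure AS and pure AZ — plus the genuine validation spectra.  Writes
per-sample verdicts and a PC1/PC2 scores plot showing the separation of the
challenges from the genuine-sample cloud.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from nirqc.config import RunConfig
from nirqc.pipeline import calibrate_api, run_specificity_screen, stage_seeds

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(seed=17)
    seeds = stage_seeds(cfg.seed)
    results = [
        calibrate_api(api, cfg, seeds[f"cal_{api}"], seeds[f"val_{api}"])
        for api in cfg.apis
    ]
    spec = run_specificity_screen(results, cfg, seeds["challenge"])
    spec["challenge_verdicts"].to_csv(OUT / "specificity_challenges.csv", index=False)
    spec["genuine_verdicts"].to_csv(OUT / "specificity_genuine.csv", index=False)

    print(f"PC1+PC2 explained variance: {spec['explained_pc12']:.3f}%")
    print(f"Challenge rejection rate: {spec['challenge_reject_rate']:.0%}")
    print(f"Genuine acceptance rate:  {spec['genuine_accept_rate']:.1%}")

    # scores plot: genuine cloud vs challenges
    pca, plan = spec["pca"], spec["plan"]
    import numpy as np

    F_train = plan._region_features(
        np.vstack([r.calibration.absorbance for r in results]), cfg.grid
    ) - plan.feature_means_
    t_train = (F_train - pca.mean) @ pca.loadings
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(t_train[:, 0], t_train[:, 1], s=12, c="tab:gray",
               label="calibration blends")
    verdicts = spec["challenge_verdicts"]
    # recompute challenge scores for plotting
    from nirqc.design import specificity_proof_set
    from nirqc.simulate import default_library, simulate_specificity_set

    challenges = simulate_specificity_set(
        specificity_proof_set(), default_library(cfg.library_seed), cfg.grid,
        cfg.noise, cfg.repacks, seed=seeds["challenge"],
    )
    F_ch = plan.transform(challenges)
    t_ch = (F_ch - pca.mean) @ pca.loadings
    for label in challenges.meta["label"].unique():
        m = (challenges.meta["label"] == label).to_numpy()
        ax.scatter(t_ch[m, 0], t_ch[m, 1], s=30, label=label)
    ax.set_xlabel("PC1 score")
    ax.set_ylabel("PC2 score")
    ax.legend(fontsize=8)
    ax.set_title("Identification library scores (challenges vs genuine)")
    fig.savefig(OUT / "specificity_scores.png", dpi=150)
    print(f"Scores plot -> {OUT / 'specificity_scores.png'}")


if __name__ == "__main__":
    main()
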
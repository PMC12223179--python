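"""GEE presence modelling on the known-coefficient simulation.

Fits the binomial logit GEE (solar and ice smooths, ship presence, and the
ship x proximity interaction spline) to a simulated 50,000-bin presence
series, compares recovered coefficients with the generating values, selects
the working correlation by QIC, and traces the ship-proximity response
curve with parametric-bootstrap confidence bands.  Writes
results/gee_recovery.csv, results/qic_comparison.csv, and
results/curve_rnv.csv; a quick-look figure goes to scratch/figures/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from narpam import synthgen as sg
from narpam.geemodel import (
    acf_cluster_size,
    bootstrap_curves,
    fit_gee,
    select_corstr,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
FIGURES = ROOT / "scratch" / "figures"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = sg.PresenceSimConfig(n_bins=50_000, seed=3)
    frame, beta, _ = sg.gen_presence_dataset(cfg)
    # the marginal ACF of this series is dominated by the seasonal covariate
    # structure (as in the field data, where decorrelation ran to thousands
    # of 5-min bins); we report it as a diagnostic and fit on the
    # generator's day-block clusters, which bound the residual correlation
    L, _ = acf_cluster_size(frame["present"])
    print(f"ACF decorrelation of the raw presence series: {L} five-minute bins")

    terms = sg.presence_terms()
    corstr, fit, qics = select_corstr(frame, terms)
    print(f"QIC independence={qics['independence']:.1f} ar1={qics['ar1']:.1f} "
          f"-> {corstr}")
    pd.DataFrame(
        {"corstr": list(qics), "qic": list(qics.values()),
         "chosen": [c == corstr for c in qics]}
    ).to_csv(RESULTS / "qic_comparison.csv", index=False)

    rec = pd.DataFrame(
        {
            "true": pd.Series(beta),
            "estimate": fit.coef,
            "se": np.sqrt(np.diag(fit.robust_cov)),
        }
    )
    rec["rel_err"] = (rec["estimate"] - rec["true"]) / rec["true"]
    rec.rename_axis("coef").to_csv(RESULTS / "gee_recovery.csv")
    print(rec.round(3).to_string())
    print(f"marginal R2 = {fit.marginal_r2:.4f}")
    print(fit.wald.round(4).to_string(index=False))

    grid = np.linspace(0.0, 40.0, 41)
    ref = {"ship_present": 1, "ice_pct": 0.0,
           "solar_deg": float(frame["solar_deg"].median())}
    curves = bootstrap_curves(fit, "rnv_km", grid, ref, n_boot=1000, seed=3)
    curves.to_csv(RESULTS / "curve_rnv.csv", index=False)

    FIGURES.mkdir(parents=True, exist_ok=True)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curves["grid"], curves["fit"], "k-", label="estimate")
    ax.fill_between(curves["grid"], curves["lo95"], curves["hi95"],
                    alpha=0.3, label="95% CI")
    ax.set_xlabel("range of nearest vessel (km)")
    ax.set_ylabel("P(acoustic presence)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(FIGURES / "curve_rnv.png", dpi=150)
    print(f"figure written to {FIGURES / 'curve_rnv.png'}")


if __name__ == "__main__":
    main()
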
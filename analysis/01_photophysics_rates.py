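"""Photophysical rate constants of GFP, tdEos and Dronpa from ensemble
bleaching traces.

Simulates normalized fluorescence decays at five laser intensities with rates
proportional to intensity (plus a spontaneous, intensity-independent
photoactivation offset for Dronpa's k_pa), fits each probe's reaction scheme,
contrasts the multi-rate schemes against single-exponential bleaching with the
nested F-test, and regresses the fitted rates on intensity.

Writes results/photophysics_fits.csv and results/photophysics_regression.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from palm_mcquant import photophysics as pp
from palm_mcquant import synth

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1

# per-unit-intensity rate coefficients and spontaneous offsets
TDEOS = {"k_ps": 0.05, "k_b": 0.15}
DRONPA = {"k_pa": 0.02, "k_pda": 0.05, "k_b": 0.3}
SPONTANEOUS_KPA = 0.008  # intensity-independent photoactivation
INTENSITIES = (0.5, 1.0, 1.5, 2.0, 3.0)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    fit_rows = []
    fits = {"tdeos": {k: [] for k in TDEOS}, "dronpa": {k: [] for k in DRONPA}}
    for inten in INTENSITIES:
        cfg = synth.DecaySimConfig(
            "tdeos", rates={k: v * inten for k, v in TDEOS.items()},
            t=np.linspace(0, 60 / inten, 200), intensity=inten, seed=SEED,
        )
        fit = pp.fit_decay(synth.simulate_decay(cfg), "tdeos",
                           fixed_fractions={"g0": 0.5, "r0": 0.5}, seed=SEED)
        cmpr = pp.compare_models(synth.simulate_decay(cfg), "tdeos", seed=SEED)
        fit_rows.append({"probe": "tdeos", "intensity": inten, **fit.params,
                         "rss": fit.rss, "f_stat": cmpr.f_stat,
                         "p_single_vs_full": cmpr.p_value})
        for k in TDEOS:
            fits["tdeos"][k].append((inten, fit))

        rates = {k: v * inten for k, v in DRONPA.items()}
        rates["k_pa"] += SPONTANEOUS_KPA
        cfg = synth.DecaySimConfig(
            "dronpa", rates=rates, t=np.linspace(0, 250 / inten, 250),
            intensity=inten, seed=SEED + 1,
        )
        fit = pp.fit_decay(synth.simulate_decay(cfg), "dronpa",
                           fixed_fractions={"a0": 0.3, "i0": 0.7}, seed=SEED)
        cmpr = pp.compare_models(synth.simulate_decay(cfg), "dronpa", seed=SEED)
        fit_rows.append({"probe": "dronpa", "intensity": inten, **fit.params,
                         "rss": fit.rss, "f_stat": cmpr.f_stat,
                         "p_single_vs_full": cmpr.p_value})
        for k in DRONPA:
            fits["dronpa"][k].append((inten, fit))

    pd.DataFrame(fit_rows).to_csv(OUT / "photophysics_fits.csv", index=False)

    reg_rows = []
    for probe, rate_fits in fits.items():
        for rate, series in rate_fits.items():
            rs = pp.rate_vs_intensity(series, rate)
            reg_rows.append({
                "probe": probe, "rate": rate, "slope": rs.slope,
                "intercept": rs.intercept,
                "intercept_stderr": rs.intercept_stderr,
                "nonzero_intercept": rs.nonzero_intercept,
            })
    reg = pd.DataFrame(reg_rows)
    reg.to_csv(OUT / "photophysics_regression.csv", index=False)

    print("Fitted rates per intensity -> results/photophysics_fits.csv")
    n_sig = sum(r["p_single_vs_full"] < 0.01 for r in fit_rows)
    print(f"Multi-rate scheme beats single-exponential (p < 0.01) for "
          f"{n_sig}/{len(fit_rows)} traces.")
    flagged = reg[reg.nonzero_intercept]
    print("Non-zero regression intercepts (spontaneous switching):",
          ", ".join(f"{r.probe}:{r.rate}" for r in flagged.itertuples()) or "none")
    return 0


if __name__ == "__main__":
    sys.exit(main())
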
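"""Extract TEER from impedance spectra by equivalent-circuit fitting.

Fits the CPE + R_s + (R_TEER || C_m) circuit to the per-condition impedance
spectra (with 2% proportional measurement noise) and tabulates the
recovered barrier resistances; also writes the Bode curves of the intact
barrier.  Results go to results/teer_fits.csv and results/bode_intact.csv.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ramanbarrier.synth import generate_impedance
from ramanbarrier.teer import bode, condition_circuits, fit_circuit

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
CONDITION_NAMES = {"T0": "intact", "T2": "EGTA 2 h", "T4": "EGTA 4 h"}


def main() -> None:
    rng = np.random.default_rng(SEED)
    f = np.logspace(0, 5, 60)
    rows = []
    for condition, circuit in condition_circuits().items():
        spec = generate_impedance(
            circuit, f, noise_fraction=0.02, rng=rng, condition=condition
        )
        fit = fit_circuit(spec)
        rows.append(
            {
                "condition": CONDITION_NAMES[condition],
                "true_r_teer_ohm_cm2": circuit.r_teer,
                "fitted_r_teer_ohm_cm2": round(fit.params.r_teer, 1),
                "fitted_r_s_ohm_cm2": round(fit.params.r_s, 2),
                "fitted_c_m_uF_cm2": round(fit.params.c_m * 1e6, 3),
                "fitted_cpe_alpha": round(fit.params.cpe_alpha, 3),
                "residual": f"{fit.residual:.2e}",
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    table.to_csv(results / "teer_fits.csv", index=False)
    print(table.to_string(index=False))
    fitted = table.fitted_r_teer_ohm_cm2.to_numpy()
    assert fitted[0] > fitted[1] > fitted[2]
    print(
        "\nbarrier resistance collapses with chelator exposure "
        f"({fitted[0]:.0f} -> {fitted[1]:.0f} -> {fitted[2]:.0f} ohm*cm^2), "
        "the impedance signature of tight-junction disassembly."
    )

    intact = generate_impedance(condition_circuits()["T0"], f, condition="T0")
    mag, phase = bode(intact)
    pd.DataFrame(
        {"frequency_hz": f, "magnitude_ohm_cm2": mag, "phase_deg": phase}
    ).to_csv(results / "bode_intact.csv", index=False)
    print("Bode curve of the intact barrier written to results/bode_intact.csv")


if __name__ == "__main__":
    main()
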
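"""Simulate the default study: 3 membranes x 20 junction spots x 3 time
points plus 40 blank-membrane spectra (220 total), and the per-condition
impedance spectra.

Raw spectra go to scratch/ (bulk output); a class/membrane summary table is
written to results/.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from ramanbarrier.io import write_dataset, write_impedance_csv
from ramanbarrier.synth import GeneratorParams, StudyDesign, generate_dataset, generate_impedance
from ramanbarrier.teer import condition_circuits

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    design = StudyDesign()
    dataset = generate_dataset(design, GeneratorParams(), seed=SEED)
    out = ROOT / "scratch" / "dataset"
    manifest = write_dataset(dataset, out)
    print(f"wrote {len(dataset)} spectra under {out}")

    summary = (
        pd.DataFrame(
            {
                "label": [s.label for s in dataset],
                "membrane": [s.membrane_id or "-" for s in dataset],
            }
        )
        .value_counts()
        .rename("n_spectra")
        .reset_index()
        .sort_values(["label", "membrane"])
    )
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    summary.to_csv(results / "dataset_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"manifest: {manifest}")

    zdir = ROOT / "scratch" / "impedance"
    zdir.mkdir(parents=True, exist_ok=True)
    for condition, circuit in condition_circuits().items():
        spec = generate_impedance(circuit, condition=condition)
        write_impedance_csv(spec, zdir / f"impedance_{condition}.csv")
    print(f"impedance fixtures (barrier resistance 700 / 328.9 / 197.9 ohm*cm^2) -> {zdir}")


if __name__ == "__main__":
    main()
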
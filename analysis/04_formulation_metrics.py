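#!/usr/bin/env python
"""Polymer characterisation and formulation arithmetic.

Computes the viscosity-average molecular weight of the mPEG-PCL
copolymer from the measured intrinsic viscosity (0.68 dL/g, chloroform,
25 degC) via Mark-Houwink-Sakurada, and demonstrates the yield /
loading / entrapment percentages on an illustrative set of weighings
(the study prints only the resulting percentages, not the weighings).
"""

import json
from pathlib import Path

from relkin import (
    FormulationWeights,
    MassPair,
    drug_loading,
    entrapment_efficiency,
    mhs_molecular_weight,
    nanoparticle_yield,
    weight_loss_percent,
)
from relkin.formulation import MPEG_PCL_CHLOROFORM

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    mv = mhs_molecular_weight(0.68, MPEG_PCL_CHLOROFORM)
    print(f"[eta] = 0.68 dL/g -> Mv = {mv:,.0f} g/mol "
          f"(k = {MPEG_PCL_CHLOROFORM.k}, a = {MPEG_PCL_CHLOROFORM.a})")

    # illustrative weighings consistent with the published percentages
    weights = FormulationWeights(
        nanoparticle_mass=70.2,
        initial_polymer_plus_drug_mass=100.0,
        drug_in_nanoparticles_mass=5.25,
        initial_drug_mass=7.0,
    )
    metrics = {
        "mv_g_per_mol": mv,
        "nanoparticle_yield_percent": nanoparticle_yield(weights),
        "drug_loading_percent": drug_loading(weights),
        "entrapment_efficiency_percent": entrapment_efficiency(weights),
        "hydrolysis_weight_loss_percent": weight_loss_percent(
            MassPair(before=100.0, after=99.4)
        ),
    }
    for key, value in metrics.items():
        print(f"{key} = {value:.6g}")
    print("note: hydrolytic weight loss stays below 1 wt% at pH 7.4 / 37 degC,"
          " so matrix erosion contributes negligibly to release")

    out = ROOT / "results" / "formulation_metrics.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(metrics, indent=2) + "\n")
    print(f"metrics written to {out}")


if __name__ == "__main__":
    main()
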
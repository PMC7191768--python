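"""Seven-strain relocation set: MFA summaries and the association matrix.

Simulates the relocation series (parental plus six movants, two on Chr2),
runs four replicate MFA experiments per strain, estimates growth rates from
logistic OD curves, and correlates the replication slope with S10 position,
S10 dosage, ori1/ter1 ratio and growth rate.  Writes
results/strain_table.tsv and results/associations.tsv.
"""

import argparse
from pathlib import Path

from s10pos.growth import normalize_mu, MuEstimate
from s10pos.pipeline import run_all


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    out = run_all(seed=args.seed)
    table = out["strain_table"]
    assoc = out["association"]
    par_mu = table.set_index("strain_id").loc["Parental", "mu_per_h"]
    table["mu_pct_of_parental"] = 100.0 * table["mu_per_h"] / par_mu

    args.outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.outdir / "strain_table.tsv", sep="\t", index=False)
    assoc.to_csv(args.outdir / "associations.tsv", sep="\t", index=False)
    print(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    print()
    print(assoc.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    print(
        "\nslope falls and dosage/ori-ter/growth decline together as S10 moves"
        " away from ori1; the slope-vs-position correlation is negative, the"
        " other three positive — the sign structure the relocation series"
        " is built to exhibit."
    )


if __name__ == "__main__":
    main()
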
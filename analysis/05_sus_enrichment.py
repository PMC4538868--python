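"""SUS comparisons across carbon sources and pathway over-representation.

Reads the per-model VIP/p(corr) tables from results/models/, builds one
shared-and-unique-structures table (and figure) per metal and sample type
comparing the biphenyl-grown model (x) against the succinate-grown model
(y), then tests VIP>0.8 hit lists from the cells models for pathway
over-representation against the identified-metabolite background. Checks
whether the spiked pathway is recovered.
"""

from pathlib import Path

import pandas as pd

from ionopls import io as iomod
from ionopls.sus_enrichment import build_sus, enrich, plot_sus, select_hits

ROOT = Path(__file__).resolve().parents[1] / "results"


def _stats(name: str) -> pd.DataFrame:
    return pd.read_csv(ROOT / "models" / f"variable_stats_{name}.tsv", sep="\t", index_col=0)


def main() -> None:
    mt = iomod.read_metabolite_table(ROOT / "qc" / "metabolite_table")
    truth = iomod.read_ground_truth(ROOT / "data" / "ground_truth.json")
    annotation = iomod.read_gmt(ROOT / "data" / "pathways.gmt")

    out = ROOT / "sus_enrichment"
    out.mkdir(parents=True, exist_ok=True)

    for metal in ("Al", "Cu"):
        for stype in ("cells", "media"):
            sus = build_sus(
                _stats(f"biphenyl_{metal}_{stype}"),
                _stats(f"succinate_{metal}_{stype}"),
                vip_threshold=0.8,
            )
            sus.to_csv(out / f"sus_{metal}_{stype}.tsv", sep="\t")
            plot_sus(sus, out / f"sus_{metal}_{stype}.png",
                     labels=(f"biphenyl {metal} {stype}", f"succinate {metal} {stype}"))
            shared = sus["category"].isin(["up_up", "down_down"]).sum()
            print(f"SUS {metal}/{stype}: {len(sus)} metabolites above threshold, "
                  f"{shared} changed the same way on both carbon sources")

    background = sorted(mt.abundances.columns[mt.identity])
    for carbon in ("biphenyl", "succinate"):
        for metal in ("Al", "Cu"):
            stats = _stats(f"{carbon}_{metal}_cells")
            hits = select_hits(stats, mt.identity, vip_threshold=0.8)
            res = enrich(hits, background, annotation, fdr_cut=0.05)
            res.to_csv(out / f"enrichment_{carbon}_{metal}_cells.tsv", sep="\t")
            top = res.index[0] if len(res) else None
            note = ""
            if (carbon, metal) == ("biphenyl", "Al"):
                note = (f"  <- spiked pathway {truth.enriched_pathway!r} "
                        f"{'recovered' if top == truth.enriched_pathway else 'NOT recovered'}")
            print(f"enrichment {carbon}/{metal} cells: {len(hits)} hits, top pathway "
                  f"{top} (FDR={res['fdr'].iloc[0]:.3g})" + note)


if __name__ == "__main__":
    main()
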
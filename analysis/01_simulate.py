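"""Generate the synthetic study dataset with known ground truth.

Writes the ion-level peak table (60 study samples + 5 blanks, 269 analytes
plus 8 spiked derivatization artifacts), the pathway annotation with one
enriched pathway, the C10-C30 alkane ladder and the ground-truth record to
results/data/.
"""

from pathlib import Path

from ionopls import io as iomod
from ionopls.synthetic import (
    generate_alkane_ladder,
    generate_design,
    generate_pathway_annotation,
    generate_peak_table,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    design = generate_design()
    table, truth = generate_peak_table(design, seed=SEED)
    annotation = generate_pathway_annotation(truth, design, seed=SEED + 1)
    ladder = generate_alkane_ladder()

    OUT.mkdir(parents=True, exist_ok=True)
    iomod.write_ion_table(table, OUT / "ion_table")
    iomod.write_gmt(annotation, OUT / "pathways.gmt")
    iomod.write_alkane_ladder(ladder, OUT / "alkane_ladder.csv")
    iomod.write_ground_truth(truth, OUT / "ground_truth.json")

    n_s, n_i = table.intensities.shape
    n_aff = sum(len(v) for v in truth.affected.values())
    print(f"wrote {n_s} samples x {n_i} ions to {OUT}")
    print(
        f"ground truth: {len(truth.corrupted_ions)} corrupted ions, "
        f"{len(truth.artifact_analytes)} artifact analytes, "
        f"{n_aff} (metabolite, condition) effects at "
        f"{truth.config.effect_size} SD, spiked pathway {truth.enriched_pathway!r}"
    )


if __name__ == "__main__":
    main()
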
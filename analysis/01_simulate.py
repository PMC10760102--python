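"""Generate the synthetic study fixture and summarise what was planted.

Writes the full fixture (peaks, genes, DE tables, expression matrix,
ranked lists, chromatin states, truth labels) under scratch/fixture and a
small summary table under results/.
"""
from pathlib import Path

import pandas as pd

from wtct import SimConfig, write_fixture

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    cfg = SimConfig(seed=SEED)
    paths = write_fixture(cfg, ROOT / "scratch" / "fixture")
    import json

    truth = json.loads(paths["truth"].read_text())
    rows = [
        ("genes", cfg.n_genes),
        ("peaks", cfg.n_peaks),
        ("designated_target_genes",
         len(truth["coupled_peaks_and_de"]["target_genes"])),
        ("coupled_genes", len(truth["coupled_peaks_and_de"]["coupled_genes"])),
        ("planted_antagonistic_genes",
         len(truth["paired_contrasts"]["antagonistic"])),
        ("expression_samples", cfg.n_samples),
        ("planted_topk_overlap",
         int(truth["ranked_lists"]["planted_overlap"])),
    ]
    out = ROOT / "results" / "01_fixture_summary.tsv"
    out.parent.mkdir(exist_ok=True)
    pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(
        out, sep="\t", index=False
    )
    print(f"fixture (seed {SEED}) written to {paths['truth'].parent}")
    for name, value in rows:
        print(f"  {name}: {value}")
    print(f"summary -> {out}")


if __name__ == "__main__":
    main()
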
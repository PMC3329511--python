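"""Generate the headline synthetic dataset (67 taxa, human record embedded)."""

from pathlib import Path

from weantime import SimConfig, simulate_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "dataset"

config = SimConfig(seed=0, include_human=True)
table, truth = simulate_dataset(config)

OUT.mkdir(parents=True, exist_ok=True)
table.write(OUT / "traits.csv")
(OUT / "tree.nwk").write_text(truth.newick + "\n")
(OUT / "truth.json").write_text(truth.to_json())
print(f"wrote {table.n}-taxon dataset to {OUT}")
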
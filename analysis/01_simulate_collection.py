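#!/usr/bin/env python
"""Generate the reference synthetic EST collection with planted ground truth.

Writes reads (FASTA), the truth table and the stub-energy structure fixtures
under results/sim/, and prints the collection composition.
"""

from pathlib import Path

from estmine.io_formats import write_fasta, write_structure_fixtures
from estmine.synthetic_data import default_study_config, simulate_collection, write_truth

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = default_study_config(SEED)
    reads, truth, fixtures = simulate_collection(config)
    write_fasta(reads, OUT / "reads.fasta")
    write_truth(truth, OUT / "truth.tsv")
    write_structure_fixtures(fixtures, OUT / "fixtures.tsv")
    counts = truth.feature_kind.value_counts().to_dict()
    print(f"seed {SEED}: {len(reads)} reads "
          f"({config.n_background} background), planted: {counts}")
    print(f"wrote {OUT}/reads.fasta, truth.tsv, fixtures.tsv")


if __name__ == "__main__":
    main()
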
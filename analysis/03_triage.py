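"""Type the non-redundant catalog: plasmid / phage / uMGE.

Writes the call table and a catalog composition summary (counts and
percentages) under results/triage/.
"""

from pathlib import Path

import pandas as pd

from aquamob import io
from aquamob.catalog import summarize_catalog
from aquamob.triage import calls_to_table, flag_mobilizable, triage

SYN = Path("results/synthetic")
CAT = Path("results/catalog")
OUT = Path("results/triage")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    ids = sorted(io.read_fasta(CAT / "nonredundant.fasta"))
    calls = triage(io.read_tsv(SYN / "annotations.tsv"),
                   io.read_tsv(SYN / "viral_evidence.tsv"), ids)
    calls = flag_mobilizable(calls, io.read_tsv(SYN / "mob_hits.tsv"))
    table = calls_to_table(calls)
    io.write_tsv(table, OUT / "type_calls.tsv")
    counts = table["label"].value_counts().to_dict()
    mobil = int(table["mobilizable"].sum())
    summary = summarize_catalog(counts, mobilizable_plasmids=mobil)
    io.write_tsv(summary, OUT / "catalog_summary.tsv")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
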
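"""Microbe-MGE association network on the prefiltered coverages, plus
congruence of positive edges with the independently derived host links.

Writes the edge table, a GraphML export and the congruence summary under
results/network/.
"""

from pathlib import Path

from aquamob import io
from aquamob.abundance import normalize_coverage
from aquamob.association import (congruence_with_hosts, infer_network,
                                 prefilter, to_graphml)

SYN = Path("results/synthetic")
TRI = Path("results/triage")
HOST = Path("results/hostlink")
OUT = Path("results/network")
SEED = 42


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rpob = io.read_tsv(SYN / "rpob.tsv").set_index("sample")["rpob"]
    mge = prefilter(normalize_coverage(
        io.read_matrix_tsv(SYN / "coverage_mge.tsv"), rpob))
    mag = prefilter(normalize_coverage(
        io.read_matrix_tsv(SYN / "coverage_mag.tsv"), rpob))
    print(f"prefilter kept {len(mge)} MGEs and {len(mag)} MAGs "
          "(well-restricted entities fall below the 25% prevalence rule)")
    edges = infer_network(mge, [mag] if len(mag) else None, seed=SEED)
    io.write_tsv(edges, OUT / "edges.tsv")
    to_graphml(edges, OUT / "network.graphml")
    n_pos = int((edges["sign"] == "positive").sum()) if len(edges) else 0
    print(f"{len(edges)} edges at q <= 0.05 ({n_pos} positive)")

    links = io.read_tsv(HOST / "host_links.tsv")
    taxonomy = io.read_tsv(SYN / "taxonomy.tsv")
    type_calls = io.read_tsv(TRI / "type_calls.tsv")
    congruence = congruence_with_hosts(edges, links, taxonomy, type_calls)
    io.write_tsv(congruence, OUT / "host_congruence.tsv")
    if len(congruence):
        print(congruence.to_string(index=False))
    else:
        print("no positive MGE-MAG edges to compare with host links")


if __name__ == "__main__":
    main()
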
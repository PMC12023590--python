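"""Community composition: rpoB normalization, presence and core MGEs,
distances, PERMANOVA by well and fraction, Procrustes and Mantel against
the MAG community.

Writes normalized matrices, core summaries, distance matrices and a
statistics report under results/abundance/.
"""

import json
from pathlib import Path

import numpy as np

from aquamob import io
from aquamob.abundance import (core_mges, distance_matrix, mantel,
                               normalize_coverage, permanova, presence,
                               procrustes_test)

SYN = Path("results/synthetic")
OUT = Path("results/abundance")
SEED = 42


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    meta = io.read_tsv(SYN / "sample_metadata.tsv")
    rpob = io.read_tsv(SYN / "rpob.tsv").set_index("sample")["rpob"]
    mge_norm = normalize_coverage(io.read_matrix_tsv(SYN / "coverage_mge.tsv"),
                                  rpob)
    mag_norm = normalize_coverage(io.read_matrix_tsv(SYN / "coverage_mag.tsv"),
                                  rpob)
    io.write_matrix_tsv(mge_norm, OUT / "mge_normalized.tsv")

    pres = presence(mge_norm, meta)
    io.write_matrix_tsv(pres, OUT / "presence.tsv")
    core = core_mges(pres, meta)
    io.write_tsv(core.counts(), OUT / "core_counts.tsv")
    print(f"core MGEs: {len(core.global_core)} global "
          f"({sorted(core.global_core)})")

    report = {}
    sample_meta = meta.set_index("sample")
    for metric in ("bray_curtis", "jaccard"):
        d = distance_matrix(mge_norm, metric)
        io.write_matrix_tsv(d, OUT / f"mge_{metric}.tsv")
        for factor in ("well", "fraction"):
            groups = sample_meta.loc[list(d.index), factor]
            f_stat, r2, p = permanova(d, groups, n_perm=999, seed=SEED)
            report[f"permanova_{metric}_{factor}"] = {
                "pseudo_F": f_stat if np.isfinite(f_stat) else "inf",
                "R2": r2, "p": p}
            print(f"PERMANOVA {metric} by {factor}: "
                  f"F={f_stat:.2f} R2={r2:.3f} p={p:.4f}")

    d_mge = distance_matrix(mge_norm, "bray_curtis")
    d_mag = distance_matrix(mag_norm, "bray_curtis")
    r, p = procrustes_test(d_mge, d_mag, n_perm=9999, seed=SEED)
    report["procrustes_mge_vs_mag"] = {"r": r, "p": p}
    print(f"Procrustes MGE vs MAG: r={r:.4f} p={p:.4f}")
    r, p = mantel(d_mge, d_mag, n_perm=9999, seed=SEED)
    report["mantel_mge_vs_mag"] = {"r": r, "p": p}
    print(f"Mantel MGE vs MAG: r={r:.4f} p={p:.4f}")
    io.write_json(report, OUT / "statistics.json")


if __name__ == "__main__":
    main()
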
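"""Generate the default synthetic groundwater community.

Writes the fixture bundle (FASTA, TSV, truth, manifest) that the later
analysis steps consume, under results/synthetic/.
"""

import sys
from pathlib import Path

from aquamob.synthetic_data import SimulationConfig, generate_community

OUT = Path("results/synthetic")


def main(seed: int = 42):
    config = SimulationConfig(seed=seed)
    bundle, truth = generate_community(config, out_dir=OUT)
    n = len(bundle.mges)
    print(f"community: {n} candidate MGEs "
          f"({config.n_plasmid} plasmids, {config.n_phage} phages, "
          f"{config.n_umge} uMGEs, {len(truth.planted_containments)} "
          f"contained copies), {len(bundle.mags)} MAGs, "
          f"{len(bundle.metadata)} samples across {config.n_wells} wells")
    print(f"planted: {len(truth.true_host)} host links, "
          f"{len(truth.planted_spacer_hits)} spacer hits, "
          f"{len(truth.planted_core_ids)} core MGEs "
          f"({len(truth.planted_env_correlated_ids)} environment-tracking)")
    print(f"wrote bundle to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 42)
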
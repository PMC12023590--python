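"""Bottom-k MinHash over canonical k-mers.

The hash is a fixed 64-bit splitmix64 finalizer applied to the 2-bit
packed canonical k-mer XORed with a constant seed, so sketches are
bit-identical across runs and platforms.  The sketch keeps the
``sketch_size`` smallest distinct hash values; the target side of a screen
uses the full (exact) hash set of the genome, mirroring query-sketch vs
target-pool screen semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: fixed seed constant folded into every hash (arbitrary, never changed)
HASH_SEED = np.uint64(0x9E2FA6C35B1D4E07)

_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i


def _encode(seq: str) -> np.ndarray:
    codes = _CODES[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains characters outside ACGT; "
                         "k-mer hashing requires an unambiguous alphabet")
    return codes


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


def canonical_kmer_hashes(seq: str, k: int) -> np.ndarray:
    """Sorted distinct hash values of all canonical k-mers of ``seq``.

    The canonical form of a k-mer is the lexicographic minimum of the
    k-mer and its reverse complement (A<C<G<T), compared as packed 2-bit
    integers, so a sequence and its reverse complement hash identically.
    """
    if not 0 < k <= 31:
        raise ValueError(f"k must be in (0, 31], got {k}")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} shorter than k={k}")
    codes = _encode(seq)
    n = len(codes) - k + 1
    fwd = np.zeros(n, dtype=np.uint64)
    rc_codes = (3 - codes)[::-1]
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        shift = np.uint64(2 * (k - 1 - j))
        fwd |= codes[j:j + n].astype(np.uint64) << shift
        rev |= rc_codes[j:j + n].astype(np.uint64) << shift
    # rc value of window i is rev-window at mirrored position
    canon = np.minimum(fwd, rev[::-1])
    hashes = _splitmix64(np.unique(canon) ^ HASH_SEED)
    return np.unique(hashes)


@dataclass(frozen=True)
class SketchParams:
    k: int = 21
    sketch_size: int = 1000
    min_shared: int = 800
    min_identity: float = 0.99

    def __post_init__(self):
        if not 0 < self.k <= 31:
            raise ValueError(f"k must be in (0, 31], got {self.k}")
        if self.sketch_size < 1:
            raise ValueError("sketch_size must be >= 1")
        if self.min_shared > self.sketch_size:
            raise ValueError("min_shared cannot exceed sketch_size")


@dataclass(frozen=True)
class MinHashSketch:
    source_id: str
    k: int
    hashes: np.ndarray  # sorted ascending, distinct

    def __len__(self):
        return len(self.hashes)


def sketch(sequence: str, params: SketchParams = SketchParams(),
           source_id: str = "") -> MinHashSketch:
    """Bottom-k sketch: the ``sketch_size`` smallest canonical-k-mer hashes."""
    hashes = canonical_kmer_hashes(sequence, params.k)
    if len(hashes) > params.sketch_size:
        hashes = np.sort(np.partition(hashes, params.sketch_size)[:params.sketch_size])
    return MinHashSketch(source_id=source_id, k=params.k, hashes=hashes)


def containment(mge_sketch: MinHashSketch, target_hashes: np.ndarray,
                k: int) -> tuple[int, float, float]:
    """(shared hashes, containment c, estimated identity c**(1/k))."""
    if mge_sketch.k != k:
        raise ValueError(f"k mismatch: sketch k={mge_sketch.k}, target k={k}")
    shared = int(np.intersect1d(mge_sketch.hashes, target_hashes,
                                assume_unique=True).size)
    c = shared / len(mge_sketch.hashes) if len(mge_sketch.hashes) else 0.0
    est_identity = c ** (1.0 / k) if c > 0 else 0.0
    return shared, c, est_identity
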
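"""Constant-weight error-correcting barcode codebooks for in situ guide readout.

Guide RNAs are read out over sequential imaging rounds in several fluorescence
channels; each guide is assigned a binary barcode of length ``n_rounds ×
n_channels`` that is "on" in exactly 4 bits (Hamming weight 4) and differs
from every other barcode in at least 4 bits (Hamming distance 4).  This
weight-4 / distance-4 structure permits single-bit error correction: a
barcode read with one dropped or one spurious bit is still uniquely nearest
to its true codeword, while two-error reads are ambiguous and discarded.

Two structural exclusions guard against systematic optical artifacts:

* a barcode must not light up in the same color channel in all 4 of its
  on-bits (channel-specific background would mimic it);
* no imaging round may contain all of its channels "on" simultaneously
  (a bright aggregate in one round would mimic it).

Blank barcodes are codewords drawn from the same constrained code but
assigned to no real guide; their detection frequency calibrates the
misidentification rate of the decoder.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ColorLayout",
    "Codebook",
    "CodebookError",
    "CapacityError",
    "generate_codebook",
    "enumerate_admissible_codewords",
]

MIN_WEIGHT = 3
MAX_WEIGHT = 5
CODE_WEIGHT = 4
MIN_DISTANCE = 4


class CodebookError(ValueError):
    """Raised for invalid codebooks, layouts or bit vectors."""


class CapacityError(CodebookError):
    """Raised when the randomized search cannot place the requested codes."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"capacity exceeded: requested {requested} codewords, "
            f"best achieved {achieved}"
        )


@dataclass(frozen=True)
class ColorLayout:
    """Rounds × channels geometry of an imaging run.

    Bit index ``b`` maps to ``(round, channel) = divmod(b, n_channels)``,
    i.e. row-major by round.
    """

    n_rounds: int
    n_channels: int

    def __post_init__(self) -> None:
        if self.n_rounds < 1 or self.n_channels < 1:
            raise CodebookError("layout requires at least 1 round and 1 channel")

    @property
    def n_bits(self) -> int:
        return self.n_rounds * self.n_channels

    def bit_round(self, bit: int) -> int:
        return bit // self.n_channels

    def bit_channel(self, bit: int) -> int:
        return bit % self.n_channels


def _admissible(bits_on: tuple[int, ...], layout: ColorLayout) -> bool:
    channels = [layout.bit_channel(b) for b in bits_on]
    if len(set(channels)) == 1:
        return False  # always lights up in the same color
    round_counts = Counter(layout.bit_round(b) for b in bits_on)
    if max(round_counts.values()) >= layout.n_channels and layout.n_channels > 1:
        return False  # some round fully on
    return True


def enumerate_admissible_codewords(layout: ColorLayout) -> np.ndarray:
    """All weight-4 vectors satisfying the channel/round exclusions.

    Returns an array of shape ``(n_candidates, n_bits)`` with dtype uint8,
    in lexicographic order of on-bit positions.
    """
    L = layout.n_bits
    out = []
    for comb in itertools.combinations(range(L), CODE_WEIGHT):
        if _admissible(comb, layout):
            v = np.zeros(L, dtype=np.uint8)
            v[list(comb)] = 1
            out.append(v)
    if not out:
        return np.zeros((0, L), dtype=np.uint8)
    return np.array(out, dtype=np.uint8)


@dataclass
class Codebook:
    """An ordered mapping identity → codeword over a fixed color layout.

    ``classes`` assigns each entry to ``targeting``, ``control`` or
    ``blank``.  Targeting and control entries together form the ``R``
    real-guide barcodes of the blank-normalized error-rate formula;
    blanks form ``B``.
    """

    layout: ColorLayout
    identities: list[str]
    classes: list[str]
    codewords: np.ndarray  # (N, n_bits) uint8

    VALID_CLASSES = ("targeting", "control", "blank")

    def __post_init__(self) -> None:
        self.codewords = np.asarray(self.codewords, dtype=np.uint8)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        n = len(self.identities)
        if len(self.classes) != n or self.codewords.shape[0] != n:
            raise CodebookError("identities, classes and codewords disagree in length")
        if self.codewords.ndim != 2 or self.codewords.shape[1] != self.layout.n_bits:
            raise CodebookError(
                f"codewords must have {self.layout.n_bits} bits per row"
            )
        if len(set(self.identities)) != n:
            dupes = [i for i, c in Counter(self.identities).items() if c > 1]
            raise CodebookError(f"duplicate identities: {dupes}")
        bad = [c for c in self.classes if c not in self.VALID_CLASSES]
        if bad:
            raise CodebookError(f"invalid identity classes: {sorted(set(bad))}")
        weights = self.codewords.sum(axis=1)
        if np.any(weights != CODE_WEIGHT):
            rows = np.nonzero(weights != CODE_WEIGHT)[0].tolist()
            raise CodebookError(
                f"codewords at rows {rows} do not have Hamming weight {CODE_WEIGHT}"
            )
        for i, row in enumerate(self.codewords):
            on = tuple(np.nonzero(row)[0])
            if not _admissible(on, self.layout):
                raise CodebookError(
                    f"codeword at row {i} violates the channel/round exclusions"
                )
        if n > 1:
            d = self.pairwise_distances()
            iu = np.triu_indices(n, 1)
            if d[iu].size and d[iu].min() < MIN_DISTANCE:
                i, j = np.unravel_index(
                    np.argmin(d + np.eye(n, dtype=int) * (2 * self.layout.n_bits)),
                    d.shape,
                )
                raise CodebookError(
                    f"codewords {i} and {j} are at Hamming distance {d[i, j]} < "
                    f"{MIN_DISTANCE}"
                )

    def pairwise_distances(self) -> np.ndarray:
        x = self.codewords.astype(np.int16)
        return np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.identities)

    @property
    def n_bits(self) -> int:
        return self.layout.n_bits

    @property
    def n_targeting(self) -> int:
        """Count of real-guide barcodes (targeting + control), the R constant."""
        return sum(c != "blank" for c in self.classes)

    @property
    def n_blank(self) -> int:
        """Count of blank barcodes, the B constant."""
        return sum(c == "blank" for c in self.classes)

    @property
    def blank_identities(self) -> set[str]:
        return {i for i, c in zip(self.identities, self.classes) if c == "blank"}

    def codeword_of(self, identity: str) -> np.ndarray:
        idx = self.identities.index(identity)
        return self.codewords[idx].copy()

    def match_bitvector(self, bits: np.ndarray) -> str | None:
        """Decode a measured bit vector to an identity, or ``None``.

        A query is decodable only when its weight is 3, 4 or 5 (one dropped
        bit, exact, or one spurious bit) and exactly one codeword lies within
        Hamming distance 1.
        """
        bits = np.asarray(bits)
        if bits.ndim != 1 or bits.shape[0] != self.layout.n_bits:
            raise CodebookError(
                f"bit-vector length error: expected {self.layout.n_bits}, "
                f"got {bits.shape}"
            )
        bits = (bits != 0).astype(np.uint8)
        weight = int(bits.sum())
        if weight < MIN_WEIGHT or weight > MAX_WEIGHT:
            return None
        dist = np.abs(self.codewords.astype(np.int16) - bits.astype(np.int16)).sum(
            axis=1
        )
        hits = np.nonzero(dist <= 1)[0]
        if hits.size != 1:
            return None
        return self.identities[int(hits[0])]

    # -- serialization ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        bitstrings = ["".join(map(str, row)) for row in self.codewords]
        return pd.DataFrame(
            {
                "identity": self.identities,
                "class": self.classes,
                "bitstring": bitstrings,
            }
        )

    def to_csv(self, path) -> None:
        """Write the codebook CSV: identity, class, bitstring; header row;
        layout recorded as a ``# layout: RxC`` comment line."""
        df = self.to_frame()
        with open(path, "w", newline="") as fh:
            fh.write(f"# layout: {self.layout.n_rounds}x{self.layout.n_channels}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "Codebook":
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# layout:"):
                spec = first.split(":", 1)[1].strip()
                n_rounds, n_channels = (int(t) for t in spec.split("x"))
                df = pd.read_csv(fh, dtype=str)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, dtype=str)
                n_rounds, n_channels = None, None
        required = {"identity", "class", "bitstring"}
        if not required.issubset(df.columns):
            raise CodebookError(
                f"malformed codebook CSV: missing columns {sorted(required - set(df.columns))}"
            )
        bitstrings = df["bitstring"].astype(str).tolist()
        lengths = {len(b) for b in bitstrings}
        if len(lengths) != 1:
            raise CodebookError("malformed codebook CSV: ragged bitstrings")
        L = lengths.pop()
        for rowno, b in enumerate(bitstrings):
            if set(b) - {"0", "1"}:
                raise CodebookError(
                    f"malformed codebook CSV: non-binary bitstring in row {rowno}"
                )
        if n_rounds is None:
            raise CodebookError("malformed codebook CSV: missing '# layout: RxC' header")
        layout = ColorLayout(n_rounds, n_channels)
        if layout.n_bits != L:
            raise CodebookError(
                f"malformed codebook CSV: layout {n_rounds}x{n_channels} does not "
                f"match bitstring length {L}"
            )
        ids = df["identity"].tolist()
        if len(set(ids)) != len(ids):
            dupes = sorted(i for i, c in Counter(ids).items() if c > 1)
            raise CodebookError(f"malformed codebook CSV: duplicate identity {dupes}")
        codewords = np.array(
            [[int(c) for c in b] for b in bitstrings], dtype=np.uint8
        )
        weights = codewords.sum(axis=1)
        bad = np.nonzero(weights != CODE_WEIGHT)[0]
        if bad.size:
            raise CodebookError(
                f"codebook CSV validation failed: rows {bad.tolist()} have "
                f"Hamming weight != {CODE_WEIGHT}"
            )
        return cls(layout, ids, df["class"].tolist(), codewords)


# convenience aliases matching the functional surface
def write_codebook(codebook: Codebook, path) -> None:
    codebook.to_csv(path)


def read_codebook(path) -> Codebook:
    return Codebook.from_csv(path)


def match_bitvector(codebook: Codebook, bits: np.ndarray) -> str | None:
    return codebook.match_bitvector(bits)


def _greedy_pass(candidates: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    order = rng.permutation(candidates.shape[0])
    accepted: list[np.ndarray] = []
    acc = np.zeros((0, candidates.shape[1]), dtype=np.uint8)
    for i in order:
        v = candidates[i]
        if acc.shape[0] == 0 or int((acc ^ v).sum(axis=1).min()) >= MIN_DISTANCE:
            accepted.append(v)
            acc = np.asarray(accepted, dtype=np.uint8)
    return acc


def generate_codebook(
    layout: ColorLayout,
    n_targets: int,
    n_blanks: int,
    seed: int,
    n_controls: int = 0,
    max_restarts: int = 200,
) -> Codebook:
    """Generate a weight-4 / distance-4 codebook under the optical exclusions.

    The admissible weight-4 vectors are enumerated once, then shuffled with a
    seeded generator and greedily accepted at pairwise distance ≥ 4.  Because
    a single greedy pass is shuffle-dependent, deterministic restart seeds are
    spawned from ``seed`` until a pass reaches the requested count (or
    ``max_restarts`` is exhausted, in which case the best pass is reported in
    the raised :class:`CapacityError`).

    Blanks are the last ``n_blanks`` accepted codewords; controls, if
    requested, the last ``n_controls`` of the preceding targeting block.
    """
    n_total = n_targets + n_blanks
    if n_total < 1:
        raise CodebookError("n_targets + n_blanks must be at least 1")
    if n_controls < 0 or n_controls > n_targets:
        raise CodebookError("n_controls must lie in [0, n_targets]")
    candidates = enumerate_admissible_codewords(layout)
    if candidates.shape[0] < n_total:
        # dominates the small-layout report: nothing can be placed anyway
        raise CapacityError(n_total, candidates.shape[0])
    if layout.n_bits < 8:
        raise CodebookError(
            f"layout too small: {layout.n_bits} bits < 8 (need room for "
            f"distance-{MIN_DISTANCE} weight-{CODE_WEIGHT} codes)"
        )

    root = np.random.default_rng(seed)
    best = np.zeros((0, layout.n_bits), dtype=np.uint8)
    chosen = None
    for _ in range(max_restarts):
        acc = _greedy_pass(candidates, np.random.default_rng(root.integers(2**31)))
        if acc.shape[0] > best.shape[0]:
            best = acc
        if acc.shape[0] >= n_total:
            chosen = acc[:n_total]
            break
    if chosen is None:
        raise CapacityError(n_total, best.shape[0])

    n_plain = n_targets - n_controls
    identities = (
        [f"guide_{i + 1:03d}" for i in range(n_plain)]
        + [f"control_{i + 1:03d}" for i in range(n_controls)]
        + [f"blank_{i + 1:03d}" for i in range(n_blanks)]
    )
    classes = ["targeting"] * n_plain + ["control"] * n_controls + ["blank"] * n_blanks
    return Codebook(layout, identities, classes, chosen)
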
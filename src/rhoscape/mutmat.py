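"""Quadra-allelic mutation transition matrices.

A mutation matrix gives, for each ancestral base (rows, order A,C,G,T), the
probability of each observed base (columns). Two flavours appear in
practice: matrices estimated from pure mutation-accumulation (MA) records,
whose diagonal is zero because every record is a change; and published
matrices that retain diagonal mass. Both are supported; for simulating
derived alleles only the off-diagonal profile matters and rows are
renormalized with the diagonal removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# Empirical C. reinhardtii transition matrix estimated from 5,710 MA single
# nucleotide mutations (rows/columns A, C, G, T). Row T sums to 0.99 from
# rounding in the source.
_PRINTED = np.array([
    [0.61, 0.11, 0.19, 0.09],
    [0.26, 0.00, 0.22, 0.52],
    [0.50, 0.22, 0.03, 0.25],
    [0.11, 0.20, 0.11, 0.57],
])

ROW_SUM_TOL = 0.015


@dataclass
class MutationMatrix:
    """4×4 ancestral→observed base transition probabilities."""

    probs: np.ndarray
    undefined_rows: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (4, 4):
            raise ValueError("mutation matrix must be 4x4")
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("entries must lie in [0, 1]")
        sums = self.probs.sum(axis=1)
        for i in range(4):
            if i in self.undefined_rows:
                continue
            if abs(sums[i] - 1.0) > ROW_SUM_TOL:
                raise ValueError(
                    f"row {BASES[i]} sums to {sums[i]:.3f}, outside 1±{ROW_SUM_TOL}")

    def row(self, base: str) -> np.ndarray:
        return self.probs[_BASE_INDEX[base]]

    def offdiagonal_rows(self) -> np.ndarray:
        """Rows with the diagonal zeroed and renormalized to sum 1.

        Rows whose off-diagonal mass is zero come back as all-NaN.
        """
        out = self.probs.copy()
        np.fill_diagonal(out, 0.0)
        s = out.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(s > 0, out / np.where(s > 0, s, 1.0), np.nan)
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("ancestral\t" + "\t".join(BASES) + "\n")
            for i, b in enumerate(BASES):
                fh.write(b + "\t" + "\t".join(f"{x:.10g}" for x in self.probs[i]) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "MutationMatrix":
        rows = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("ancestral"):
                raise ValueError("expected header line starting with 'ancestral'")
            for line in fh:
                tok = line.split()
                if not tok:
                    continue
                rows[tok[0]] = [float(x) for x in tok[1:5]]
        probs = np.array([rows[b] for b in BASES])
        return cls(probs)


def load_printed_matrix() -> MutationMatrix:
    """The published C. reinhardtii MA-based mutation matrix, verbatim."""
    return MutationMatrix(_PRINTED.copy())


def estimate_matrix(mutations) -> MutationMatrix:
    """Estimate transition probabilities from (ancestral, derived) records.

    Each row is the relative frequency of derived bases among records with
    that ancestral base; rows with no records are flagged undefined (zeros).
    Input order does not matter.
    """
    records = list(mutations)
    if not records:
        raise ValueError("empty mutation list")
    counts = np.zeros((4, 4))
    for anc, der in records:
        counts[_BASE_INDEX[anc.upper()], _BASE_INDEX[der.upper()]] += 1
    totals = counts.sum(axis=1)
    undefined = frozenset(int(i) for i in np.flatnonzero(totals == 0))
    probs = np.zeros((4, 4))
    nz = totals > 0
    probs[nz] = counts[nz] / totals[nz, None]
    return MutationMatrix(probs, undefined_rows=undefined)


def write_mutation_list(mutations, path) -> None:
    with open(path, "w") as fh:
        fh.write("ancestral\tderived\n")
        for anc, der in mutations:
            fh.write(f"{anc}\t{der}\n")


def read_mutation_list(path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("ancestral"):
            raise ValueError("expected header 'ancestral\\tderived'")
        for line in fh:
            tok = line.split()
            if tok:
                out.append((tok[0], tok[1]))
    return out
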
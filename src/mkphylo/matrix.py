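"""Categorical character matrices (morphology-like data) and their I/O.

States are small non-negative integers 0..k-1 with k = 2 (binary) or 4
(multistate) per character; -1 encodes missing ("?").  Simulated matrices
never contain missing entries, but matrices read from NEXUS/PHYLIP may.
Format reading and writing delegates to dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MISSING = -1
_SYMBOLS = "0123"


@dataclass
class CharacterMatrix:
    """taxa x characters matrix of categorical states.

    Attributes
    ----------
    taxa : ordered taxon names (rows).
    data : int8 array (n_taxa, n_chars); -1 means missing.
    k_per_char : int array of declared state-space sizes (2 or 4).
    provenance : free-form record of how the matrix was produced
        (e.g. the dataset-level rate, gamma shape and seed of a
        simulation), or None for externally supplied data.
    """

    taxa: list[str]
    data: np.ndarray
    k_per_char: np.ndarray
    provenance: Optional[dict] = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        self.k_per_char = np.asarray(self.k_per_char, dtype=np.int8)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (taxa x characters)")
        if len(self.taxa) != self.data.shape[0]:
            raise ValueError("taxa count does not match data rows")
        if self.k_per_char.shape != (self.data.shape[1],):
            raise ValueError("k_per_char length does not match character count")
        if np.any((self.data >= self.k_per_char[None, :]) & (self.data != MISSING)):
            raise ValueError("state outside declared state space")
        if np.any((self.data < 0) & (self.data != MISSING)):
            raise ValueError("negative state code")

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_chars(self) -> int:
        return self.data.shape[1]

    @property
    def n_binary(self) -> int:
        return int(np.sum(self.k_per_char == 2))

    @property
    def n_multistate(self) -> int:
        return int(np.sum(self.k_per_char > 2))

    def column(self, j: int) -> np.ndarray:
        return self.data[:, j]

    def resample_characters(self, rng: np.random.Generator) -> "CharacterMatrix":
        """Nonparametric bootstrap pseudo-replicate: characters drawn
        with replacement, same total count."""
        idx = rng.integers(0, self.n_chars, size=self.n_chars)
        return CharacterMatrix(
            list(self.taxa), self.data[:, idx], self.k_per_char[idx],
            provenance={"bootstrap_of": self.provenance},
        )


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

def _row_string(row: np.ndarray) -> str:
    return "".join("?" if s == MISSING else _SYMBOLS[s] for s in row)


def write_nexus(matrix: CharacterMatrix, path) -> None:
    """Write DATATYPE=STANDARD NEXUS with SYMBOLS="0123" and MISSING=?."""
    import dendropy

    taxa = dendropy.TaxonNamespace(matrix.taxa)
    cm = dendropy.StandardCharacterMatrix(taxon_namespace=taxa)
    cm.default_state_alphabet = dendropy.new_standard_state_alphabet(_SYMBOLS)
    for name, row in zip(matrix.taxa, matrix.data):
        cm.new_sequence(taxa.get_taxon(name), _row_string(row))
    cm.write(path=str(path), schema="nexus")


def read_nexus(path, k_mode: str = "implied") -> CharacterMatrix:
    """Read a standard-datatype NEXUS matrix.

    k_mode="implied" declares each character's state-space size as the
    number of distinct observed states (minimum 2, MrBayes-style);
    k_mode="max4" declares every character as 4-state.
    """
    import dendropy

    cm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    taxa = [t.label for t in cm.taxon_namespace]
    rows = []
    for t in cm.taxon_namespace:
        seq = cm[t]
        row = []
        for cell in seq:
            sym = str(cell.symbol) if hasattr(cell, "symbol") else str(cell)
            row.append(MISSING if sym in "?-" else int(sym))
        rows.append(row)
    data = np.asarray(rows, dtype=np.int8)
    return CharacterMatrix(taxa, data, _declare_k(data, k_mode))


def _declare_k(data: np.ndarray, k_mode: str) -> np.ndarray:
    if k_mode == "max4":
        return np.full(data.shape[1], 4, dtype=np.int8)
    if k_mode != "implied":
        raise ValueError(f"unknown k_mode {k_mode!r}")
    ks = []
    for j in range(data.shape[1]):
        col = data[:, j]
        observed = col[col != MISSING]
        kj = int(observed.max()) + 1 if observed.size else 2
        ks.append(max(2, kj))
    return np.asarray(ks, dtype=np.int8)


def write_phylip(matrix: CharacterMatrix, path) -> None:
    """Relaxed PHYLIP: header line then whitespace-separated name + row."""
    with open(path, "w") as fh:
        fh.write(f"{matrix.n_taxa} {matrix.n_chars}\n")
        for name, row in zip(matrix.taxa, matrix.data):
            fh.write(f"{name}  {_row_string(row)}\n")


def read_phylip(path, k_mode: str = "implied") -> CharacterMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        n_taxa, n_chars = int(header[0]), int(header[1])
        taxa, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            seq = seq.strip().replace(" ", "")
            taxa.append(name)
            rows.append([MISSING if c in "?-" else int(c) for c in seq])
    data = np.asarray(rows, dtype=np.int8)
    if data.shape != (n_taxa, n_chars):
        raise ValueError(
            f"PHYLIP header promises {n_taxa}x{n_chars}, file contains {data.shape}"
        )
    return CharacterMatrix(taxa, data, _declare_k(data, k_mode))


def read_matrix(path, k_mode: str = "implied") -> CharacterMatrix:
    """Dispatch on file content: NEXUS if the file starts with #NEXUS."""
    with open(path) as fh:
        head = fh.read(6)
    if head.upper().startswith("#NEXUS"):
        return read_nexus(path, k_mode=k_mode)
    return read_phylip(path, k_mode=k_mode)
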
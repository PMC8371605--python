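"""Multiple sequence alignment handling.

Covers A3M/Stockholm/FASTA parsing, effective-depth (N_eff) weighting,
cluster subsampling for the trunk input, BERT-style masking of alignment
entries, and the initial embedding of the MSA into the network's MSA and
pair representations.

Alphabet: the 20 amino acids, ``X`` (unknown), ``-`` (gap) and a MASK token
— 23 input classes; reconstruction of masked entries is predicted over the
22 non-MASK classes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .chemistry import RESTYPES
from .config import ModelConfig

__all__ = [
    "ALPHABET", "GAP_INDEX", "MASK_INDEX", "N_INPUT_CLASSES", "N_OUTPUT_CLASSES",
    "Msa", "MaskedMsa", "NeffProfile",
    "parse_a3m", "write_a3m", "parse_fasta", "parse_stockholm",
    "compute_neff", "mask_msa", "subsample_clusters", "initial_representations",
]

ALPHABET = RESTYPES + "X-"          # indices 0..19 residues, 20 X, 21 gap
MASK_INDEX = len(ALPHABET)           # 22
GAP_INDEX = ALPHABET.index("-")
X_INDEX = ALPHABET.index("X")
N_INPUT_CLASSES = 23                 # incl. MASK
N_OUTPUT_CLASSES = 22                # reconstruction target classes (no MASK)

_CHAR_TO_INDEX = {c: i for i, c in enumerate(ALPHABET)}


def encode(sequence: str) -> np.ndarray:
    return np.array([_CHAR_TO_INDEX.get(c, X_INDEX) for c in sequence], dtype=np.int64)


class MsaParseError(ValueError):
    pass


@dataclass
class Msa:
    """Aligned sequences (query first) plus per-position deletion counts.

    ``deletions[s, j]`` counts the insertions (lowercase letters in A3M)
    in sequence ``s`` immediately preceding aligned column ``j``. The query
    row contains no gaps after A3M normalization.
    """

    sequences: list[str]
    deletions: np.ndarray            # (N_seq, N_res) int
    descriptions: list[str] | None = None

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise MsaParseError(f"ragged alignment: lengths {sorted(lengths)}")
        self.deletions = np.asarray(self.deletions, dtype=np.int64)
        if self.deletions.shape != (self.n_seq, self.n_res):
            raise MsaParseError("deletion matrix shape mismatch")

    @property
    def n_seq(self) -> int:
        return len(self.sequences)

    @property
    def n_res(self) -> int:
        return len(self.sequences[0])

    @property
    def query(self) -> str:
        return self.sequences[0]

    def array(self) -> np.ndarray:
        """(N_seq, N_res) integer codes."""
        return np.stack([encode(s) for s in self.sequences])

    def subset(self, rows) -> "Msa":
        rows = list(rows)
        return Msa(
            [self.sequences[r] for r in rows],
            self.deletions[rows],
            [self.descriptions[r] for r in rows] if self.descriptions else None,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Msa)
            and self.sequences == other.sequences
            and np.array_equal(self.deletions, other.deletions)
        )


# -- parsing ---------------------------------------------------------------

def _read_fasta_records(text: str) -> list[tuple[str, str]]:
    records, header, chunks = [], None, []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if header is not None:
                records.append((header, "".join(chunks)))
            header, chunks = line[1:], []
        else:
            if header is None:
                raise MsaParseError("sequence data before first header")
            chunks.append(line)
    if header is not None:
        records.append((header, "".join(chunks)))
    if not records:
        raise MsaParseError("no records found")
    return records


def parse_a3m(text: str) -> Msa:
    """Parse A3M: lowercase letters are insertions relative to the query;
    they are removed from the aligned columns and counted as deletions
    assigned to the following aligned column."""
    records = _read_fasta_records(text)
    sequences, deletion_rows, descriptions = [], [], []
    n_res = None
    for header, raw in records:
        aligned, deletions, pending = [], [], 0
        for ch in raw:
            if ch.islower():
                pending += 1
            else:
                aligned.append(ch.upper())
                deletions.append(pending)
                pending = 0
        if n_res is None:
            n_res = len(aligned)
            if "-" in aligned:
                raise MsaParseError("query row contains gaps")
        elif len(aligned) != n_res:
            raise MsaParseError(
                f"row {header!r} has {len(aligned)} aligned columns, query has {n_res}"
            )
        sequences.append("".join(aligned))
        deletion_rows.append(deletions)
        descriptions.append(header)
    return Msa(sequences, np.array(deletion_rows), descriptions)


def write_a3m(msa: Msa) -> str:
    """Inverse of :func:`parse_a3m` up to the identity of inserted letters
    (written as lowercase ``a``); deletion counts round-trip exactly."""
    out = io.StringIO()
    descriptions = msa.descriptions or [f"seq{i}" for i in range(msa.n_seq)]
    for s in range(msa.n_seq):
        out.write(f">{descriptions[s]}\n")
        row = []
        for j, ch in enumerate(msa.sequences[s]):
            row.append("a" * int(msa.deletions[s, j]))
            row.append(ch)
        out.write("".join(row) + "\n")
    return out.getvalue()


def parse_fasta(text: str) -> Msa:
    """Read an (unaligned) FASTA query or a gapless alignment."""
    return parse_a3m(text)


def parse_stockholm(text: str) -> Msa:
    """Read a Stockholm alignment (via Bio.AlignIO); columns gapped in the
    query are treated as insertions, matching the A3M normalization."""
    from Bio import AlignIO

    alignment = AlignIO.read(io.StringIO(text), "stockholm")
    rows = [str(rec.seq).replace(".", "-").upper() for rec in alignment]
    keep = [j for j, c in enumerate(rows[0]) if c != "-"]
    sequences, deletion_rows = [], []
    for row in rows:
        aligned, deletions, pending = [], [], 0
        for j, ch in enumerate(row):
            if j in set(keep):
                aligned.append(ch)
                deletions.append(pending)
                pending = 0
            elif ch != "-":
                pending += 1
        sequences.append("".join(aligned))
        deletion_rows.append(deletions)
    return Msa(sequences, np.array(deletion_rows), [r.id for r in alignment])


# -- effective depth -------------------------------------------------------

@dataclass
class NeffProfile:
    """Per-sequence weights and per-position effective alignment depth."""

    weights: np.ndarray        # (N_seq,), each in (0, 1]
    per_position: np.ndarray   # (N_res,) nonnegative
    median: float


def sequence_identity(codes: np.ndarray, i: int, j: int) -> float:
    """Fractional identity over the region non-gap in either sequence."""
    a, b = codes[i], codes[j]
    either = (a != GAP_INDEX) | (b != GAP_INDEX)
    denom = int(either.sum())
    if denom == 0:
        return 0.0
    matches = int(((a == b) & (a != GAP_INDEX) & either).sum())
    return matches / denom


def compute_neff(msa: Msa, identity_threshold: float = 0.8) -> NeffProfile:
    """Effective-depth weighting.

    Each sequence's weight is one over the number of sequences (itself
    included) with ≥ ``identity_threshold`` identity, measured on the region
    that is non-gap in either sequence. The per-position depth sums the
    weights of sequences that are non-gap at that position.
    """
    if msa.n_seq == 0:
        raise ValueError("empty MSA")
    codes = msa.array()
    nongap = codes != GAP_INDEX
    s = msa.n_seq
    counts = np.zeros(s, dtype=np.int64)
    # pairwise identity, vectorized one row at a time
    for i in range(s):
        both = (codes[i] == codes) & nongap[i][None, :] & nongap
        either = nongap[i][None, :] | nongap
        denom = either.sum(axis=1)
        matches = (both & either).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            identity = np.where(denom > 0, matches / np.maximum(denom, 1), 0.0)
        counts[i] = int((identity >= identity_threshold).sum())
    weights = 1.0 / counts
    per_position = (weights[:, None] * nongap).sum(axis=0)
    return NeffProfile(weights, per_position, float(np.median(per_position)))


# -- BERT-style masking ----------------------------------------------------

@dataclass
class MaskedMsa:
    """MSA with corrupted entries and the reconstruction targets.

    ``codes`` is the corrupted (N_seq, N_res) class array (may contain the
    MASK token); targets exist exactly at the corrupted positions.
    """

    msa: Msa
    codes: np.ndarray            # (N_seq, N_res) int, corrupted
    target_positions: np.ndarray  # (K, 2) row/col of corrupted entries
    target_classes: np.ndarray    # (K,) original class at those entries

    @property
    def target_mask(self) -> np.ndarray:
        m = np.zeros(self.codes.shape, dtype=bool)
        m[self.target_positions[:, 0], self.target_positions[:, 1]] = True
        return m


def mask_msa(msa: Msa, mask_fraction: float = 0.12, mutate_fraction: float = 0.03,
             seed: int = 0) -> MaskedMsa:
    """Randomly corrupt alignment entries for the BERT-style objective.

    A position is selected with probability ``mask_fraction +
    mutate_fraction``; selected positions are replaced by the MASK token or
    by a residue drawn uniformly from the 20 amino acids, in proportion to
    the two fractions. Reproducible under a fixed seed.
    """
    if not (0 <= mask_fraction <= 1 and 0 <= mutate_fraction <= 1
            and mask_fraction + mutate_fraction <= 1):
        raise ValueError("fractions must be in [0,1] with sum <= 1")
    rng = np.random.default_rng(seed)
    codes = msa.array()
    u = rng.random(codes.shape)
    selected = u < (mask_fraction + mutate_fraction)
    to_mask = selected & (u < mask_fraction)
    to_mutate = selected & ~to_mask
    corrupted = codes.copy()
    corrupted[to_mask] = MASK_INDEX
    corrupted[to_mutate] = rng.integers(0, 20, size=int(to_mutate.sum()))
    rows, cols = np.nonzero(selected)
    return MaskedMsa(
        msa=msa,
        codes=corrupted,
        target_positions=np.stack([rows, cols], axis=1),
        target_classes=codes[rows, cols],
    )


# -- cluster subsampling ---------------------------------------------------

def subsample_clusters(msa: Msa, n_clusters: int, seed: int = 0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Choose cluster centres uniformly without replacement (query forced)
    and assign every remaining sequence to its nearest centre by identity.

    Returns ``(centre_indices, assignment)`` where ``assignment[s]`` is the
    centre index (into the MSA) owning sequence ``s``. ``n_clusters`` is
    clamped to the number of sequences. Deterministic under the seed.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = np.random.default_rng(seed)
    s = msa.n_seq
    n_clusters = min(n_clusters, s)
    others = rng.permutation(np.arange(1, s))[: n_clusters - 1]
    centres = np.concatenate([[0], np.sort(others)]).astype(np.int64)
    codes = msa.array()
    assignment = np.empty(s, dtype=np.int64)
    centre_set = set(centres.tolist())
    for i in range(s):
        if i in centre_set:
            assignment[i] = i
            continue
        best_c, best_id = centres[0], -1.0
        for c in centres:
            ident = sequence_identity(codes, i, int(c))
            if ident > best_id:
                best_c, best_id = int(c), ident
        assignment[i] = best_c
    return centres, assignment


# -- initial representations -----------------------------------------------

def _deletion_features(deletions: np.ndarray) -> np.ndarray:
    """Two features per entry: has-deletion flag and an arctan squash of the
    raw count into [0, 1)."""
    has = (deletions > 0).astype(np.float64)
    value = (2.0 / np.pi) * np.arctan(deletions / 3.0)
    return np.stack([has, value], axis=-1)


def msa_feature_array(codes: np.ndarray, deletions: np.ndarray) -> np.ndarray:
    """One-hot classes plus deletion features: (N_seq, N_res, 25)."""
    onehot = np.eye(N_INPUT_CLASSES)[codes]
    return np.concatenate([onehot, _deletion_features(deletions)], axis=-1)


def initial_representations(msa_or_masked, store, cfg: ModelConfig):
    """Embed an (optionally masked) MSA into the trunk's two representations.

    The MSA representation is a linear embedding of one-hot classes plus
    deletion features, (N_seq, N_res, c_m). The pair representation is
    built from query-residue embeddings of both endpoints plus a clipped
    relative-position encoding, (N_res, N_res, c_z).
    """
    from . import nn

    if isinstance(msa_or_masked, MaskedMsa):
        codes, deletions = msa_or_masked.codes, msa_or_masked.msa.deletions
        query_codes = msa_or_masked.msa.array()[0]
    else:
        codes, deletions = msa_or_masked.array(), msa_or_masked.deletions
        query_codes = codes[0]
    feats = msa_feature_array(codes, deletions)
    d_feat = feats.shape[-1]
    m = nn.linear(store, "embed.msa", nn.astensor(feats), d_feat, cfg.c_m)

    n_res = codes.shape[1]
    query_onehot = np.eye(N_INPUT_CLASSES)[query_codes]
    left = nn.linear(store, "embed.pair_left", nn.astensor(query_onehot),
                     N_INPUT_CLASSES, cfg.c_z)
    right = nn.linear(store, "embed.pair_right", nn.astensor(query_onehot),
                      N_INPUT_CLASSES, cfg.c_z)
    z = left.reshape(n_res, 1, cfg.c_z) + right.reshape(1, n_res, cfg.c_z)

    offsets = np.arange(n_res)[:, None] - np.arange(n_res)[None, :]
    clipped = np.clip(offsets, -cfg.rel_pos_clip, cfg.rel_pos_clip) + cfg.rel_pos_clip
    n_rel = 2 * cfg.rel_pos_clip + 1
    rel = np.eye(n_rel)[clipped]
    z = z + nn.linear(store, "embed.relpos", nn.astensor(rel), n_rel, cfg.c_z)
    return m, z
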
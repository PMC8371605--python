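"""Synthetic data generation: toy proteins, simulated MSAs, perturbations,
and the chain-level curation rules applied to generic metadata records.

Everything here is seed-deterministic and generated in-process, so every
other module can be exercised without downloading any real data. Toy
backbones are built from ideal bond lengths/angles with canonical motif
torsions (helix φ/ψ = −57°/−47°, strand −120°/120°); side chains sit at
the template default rotamers, so a freshly generated structure has zero
stereochemical violation by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import (
    IDEAL_C_N, IDEAL_C_O, IDEAL_CA_C, IDEAL_CA_C_N, IDEAL_CA_C_O,
    IDEAL_C_N_CA, IDEAL_N_CA, IDEAL_N_CA_C, Protein, RESTYPES,
    residue_template,
)
from .geometry import place_atom as _place_atom, rigid_from_three_points
from .msa import Msa
from .structure import TorsionSet, build_all_atom

__all__ = [
    "make_toy_structure", "make_synthetic_msa", "perturb_structure",
    "ChainRecord", "filter_chain_records", "make_synthetic_chain_records",
]

MOTIF_TORSIONS = {"helix": (-57.0, -47.0), "strand": (-120.0, 120.0)}


def _motif_phi_psi(n_res: int, motif: str) -> tuple[np.ndarray, np.ndarray]:
    if motif in MOTIF_TORSIONS:
        phi, psi = MOTIF_TORSIONS[motif]
        return np.full(n_res, phi), np.full(n_res, psi)
    if motif == "mixed":
        kinds = ["helix" if (i // 8) % 2 == 0 else "strand" for i in range(n_res)]
        # extended torsions on the two residues before each boundary so the
        # chain opens up before changing secondary structure instead of
        # turning sharply into its own previous turn
        boundaries = [i for i in range(n_res - 1) if kinds[i] != kinds[i + 1]]
        for i in boundaries:
            kinds[i] = "strand"
            if i > 0:
                kinds[i - 1] = "strand"
        phi = np.array([MOTIF_TORSIONS[k][0] for k in kinds])
        psi = np.array([MOTIF_TORSIONS[k][1] for k in kinds])
        return phi, psi
    raise ValueError(f"unknown motif {motif!r}")


def make_toy_structure(n_res: int, motif: str = "helix", seed: int = 0,
                       sequence: str | None = None) -> tuple[str, Protein]:
    """Ideal-geometry toy protein with canonical motif torsions.

    The backbone is chained with ideal bond lengths and angles (ω = 180°);
    per-residue frames are built from the N/CA/C atoms and all atoms are
    placed from the residue templates at default rotamers. Default random
    sequences exclude proline — a helix breaker whose ring constrains φ,
    which an idealized motif backbone cannot honour — but an explicit
    ``sequence`` may contain it.
    """
    if n_res < 4:
        raise ValueError("n_res must be >= 4")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice([r for r in RESTYPES if r != "P"], size=n_res))
    elif len(sequence) != n_res:
        raise ValueError("sequence length mismatch")
    phi, psi = _motif_phi_psi(n_res, motif)

    n_atoms = np.zeros((n_res, 3))
    ca_atoms = np.zeros((n_res, 3))
    c_atoms = np.zeros((n_res, 3))
    ang = np.radians(IDEAL_N_CA_C)
    n_atoms[0] = [0.0, 0.0, 0.0]
    ca_atoms[0] = [IDEAL_N_CA, 0.0, 0.0]
    c_atoms[0] = ca_atoms[0] + IDEAL_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    for i in range(1, n_res):
        n_atoms[i] = _place_atom(n_atoms[i - 1], ca_atoms[i - 1], c_atoms[i - 1],
                                 IDEAL_C_N, IDEAL_CA_C_N, psi[i - 1])
        ca_atoms[i] = _place_atom(ca_atoms[i - 1], c_atoms[i - 1], n_atoms[i],
                                  IDEAL_N_CA, IDEAL_C_N_CA, 180.0)
        c_atoms[i] = _place_atom(c_atoms[i - 1], n_atoms[i], ca_atoms[i],
                                 IDEAL_CA_C, IDEAL_N_CA_C, phi[i])

    frames = rigid_from_three_points(n_atoms, ca_atoms, c_atoms)
    angles = np.zeros((n_res, 4))
    mask = np.zeros((n_res, 4), bool)
    for i, r in enumerate(sequence):
        tmpl = residue_template(r)
        mask[i] = tmpl.chi_valid
        angles[i] = default_rotamer(r)
    torsions = TorsionSet(angles, mask)
    protein = build_all_atom(sequence, frames, torsions)
    protein = _resolve_clashes(sequence, frames, torsions, protein)
    return sequence, protein


#: residues whose χ2 sits near ±90° in the common rotamer (aromatic rings)
_AROMATIC = set("HFYW")


def default_rotamer(res1: str) -> np.ndarray:
    """Canonical extended rotamer: χ1 = −60° (g−), distal χ = 180° (trans),
    aromatic χ2 = 90° — keeps side chains pointing away from the backbone."""
    chi = np.array([-60.0, 180.0, 180.0, 180.0])
    if res1 in _AROMATIC:
        chi[1] = 90.0
    return chi


def _clash_pairs(protein: Protein, overlap: float = 1.5) -> list[tuple[int, int]]:
    from .chemistry import VDW_RADII

    pos, res, rad, name = [], [], [], []
    for i, r in enumerate(protein.sequence):
        tmpl = residue_template(r)
        for k, nm in enumerate(tmpl.atom_names):
            if protein.atom_mask[i, k]:
                pos.append(protein.atom_positions[i, k])
                res.append(i)
                rad.append(VDW_RADII.get(tmpl.elements[k], 1.7))
                name.append(nm)
    pos = np.asarray(pos)
    res = np.asarray(res)
    rad = np.asarray(rad)
    d = np.linalg.norm(pos[:, None] - pos[None], axis=-1)
    cutoff = rad[:, None] + rad[None, :] - overlap
    bad = np.triu((d < cutoff) & (res[:, None] != res[None, :]), k=1)
    out = set()
    for a, b in np.argwhere(bad):
        if res[b] == res[a] + 1 and name[a] == "C" and name[b] == "N":
            continue
        out.add((int(res[a]), int(res[b])))
    return sorted(out)


_CHI1_CHOICES = (-60.0, 180.0, 60.0)
_CHI2_CHOICES = (180.0, 90.0, -90.0, -60.0, 60.0)


def _resolve_clashes(sequence: str, frames, torsions: TorsionSet,
                     protein: Protein, max_rounds: int = 12) -> Protein:
    """Greedy deterministic rotamer search: for residues involved in a
    steric clash, try alternative standard χ1/χ2 rotamers until the
    structure is clash-free. Torsion changes are committed in place."""
    for _ in range(max_rounds):
        clashes = _clash_pairs(protein)
        if not clashes:
            return protein
        i, j = clashes[0]
        n_before = len(clashes)
        improved = False
        for target in (j, i):
            if not torsions.mask[target].any():
                continue
            for chi1 in _CHI1_CHOICES:
                for chi2 in _CHI2_CHOICES:
                    trial = torsions.angles.copy()
                    trial[target, 0] = chi1
                    if torsions.mask[target, 1]:
                        trial[target, 1] = chi2
                    cand = build_all_atom(
                        sequence, frames, TorsionSet(trial, torsions.mask)
                    )
                    if len(_clash_pairs(cand)) < n_before:
                        torsions.angles[:] = trial
                        protein = cand
                        improved = True
                        break
                if improved:
                    break
            if improved:
                break
        if not improved:
            break
    return protein


def make_synthetic_msa(sequence: str, n_seqs: int, mutation_rate: float = 0.2,
                       gap_rate: float = 0.05, seed: int = 0) -> Msa:
    """Simulated alignment: i.i.d. substitutions and gaps per position,
    query preserved as the first row."""
    if not (0 <= mutation_rate <= 1 and 0 <= gap_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_res = len(sequence)
    rows = [sequence]
    aa = list(RESTYPES)
    for _ in range(n_seqs - 1):
        chars = []
        for c in sequence:
            u = rng.random()
            if u < gap_rate:
                chars.append("-")
            elif u < gap_rate + mutation_rate:
                chars.append(str(rng.choice(aa)))
            else:
                chars.append(c)
        rows.append("".join(chars))
    return Msa(rows, np.zeros((n_seqs, n_res), int),
               [f"synthetic{i}" for i in range(n_seqs)])


def perturb_structure(protein: Protein, noise: float = 0.0,
                      outlier_fraction: float = 0.0, seed: int = 0) -> Protein:
    """Gaussian displacement of every atom plus large (50 Å) displacements
    of a chosen fraction of residues — drives the metric oracles."""
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    pos = protein.atom_positions.copy()
    if noise > 0:
        pos += rng.normal(scale=noise, size=pos.shape)
    if outlier_fraction > 0:
        n = len(protein)
        k = int(round(outlier_fraction * n))
        which = rng.choice(n, size=k, replace=False)
        for i in which:
            shift = rng.normal(size=3)
            shift = 50.0 * shift / np.linalg.norm(shift)
            pos[i] += shift
    return Protein(protein.sequence, pos, protein.atom_mask.copy())


# -- chain-record curation --------------------------------------------------

@dataclass
class ChainRecord:
    """Minimal chain metadata needed by the curation rules."""

    chain_id: str
    release_date: str        # ISO yyyy-mm-dd
    sequence: str
    resolved_count: int
    resolved_ca: int
    method: str              # e.g. XRAY, EM, NMR
    resolution: float        # Å (lower is better)
    cluster_id: int          # 40%-identity cluster


class RecordFieldError(ValueError):
    pass


_REQUIRED = ("chain_id", "release_date", "sequence", "resolved_count",
             "resolved_ca", "method", "resolution", "cluster_id")


def filter_chain_records(records: list[ChainRecord],
                         date_cutoff: str = "2018-04-30",
                         standard_alphabet: str = RESTYPES + "X",
                         ) -> tuple[list[ChainRecord], dict]:
    """Apply the chain-curation rules in order, counting attrition per rule.

    Order: release-date cutoff; single-amino-acid-type sequences; ambiguous
    chemical components (non-standard residue codes); exact-duplicate
    deduplication keeping the most resolved Cα; fewer than 16 resolved
    residues; unknown (X) residues; NMR entries; best resolution per
    cluster; fewer than 80 resolved Cα; more than 1,400 residues.
    """
    for rec in records:
        for f in _REQUIRED:
            if getattr(rec, f, None) is None:
                raise RecordFieldError(f"record {rec!r} missing field {f!r}")

    counts: dict[str, int] = {}
    kept = list(records)

    def drop(rule: str, keep_fn):
        nonlocal kept
        before = len(kept)
        kept = [r for r in kept if keep_fn(r)]
        counts[rule] = before - len(kept)

    drop("release_date", lambda r: r.release_date > date_cutoff)
    drop("single_residue_type", lambda r: len(set(r.sequence)) > 1)
    drop("ambiguous_component",
         lambda r: all(c in standard_alphabet for c in r.sequence))

    before = len(kept)
    best_by_seq: dict[str, ChainRecord] = {}
    order = []
    for r in kept:
        cur = best_by_seq.get(r.sequence)
        if cur is None:
            best_by_seq[r.sequence] = r
            order.append(r.sequence)
        elif r.resolved_ca > cur.resolved_ca:
            best_by_seq[r.sequence] = r
    kept = [best_by_seq[s] for s in order]
    counts["exact_duplicate"] = before - len(kept)

    drop("min_16_resolved", lambda r: r.resolved_count >= 16)
    drop("unknown_residues", lambda r: "X" not in r.sequence)
    drop("nmr", lambda r: r.method.upper() != "NMR")

    before = len(kept)
    best_by_cluster: dict[int, ChainRecord] = {}
    cluster_order = []
    for r in kept:
        cur = best_by_cluster.get(r.cluster_id)
        if cur is None:
            best_by_cluster[r.cluster_id] = r
            cluster_order.append(r.cluster_id)
        elif r.resolution < cur.resolution:
            best_by_cluster[r.cluster_id] = r
    kept = [best_by_cluster[c] for c in cluster_order]
    counts["cluster_best_resolution"] = before - len(kept)

    drop("min_80_resolved_ca", lambda r: r.resolved_ca >= 80)
    drop("max_1400_residues", lambda r: len(r.sequence) <= 1400)

    counts["total_removed"] = len(records) - len(kept)
    return kept, counts


def make_synthetic_chain_records(n: int = 200, seed: int = 0) -> list[ChainRecord]:
    """Random metadata records straddling every curation threshold."""
    rng = np.random.default_rng(seed)
    records = []
    aa = list(RESTYPES)
    for i in range(n):
        length = int(rng.integers(8, 1600))
        seq = "".join(rng.choice(aa, size=length))
        if rng.random() < 0.05:
            seq = "A" * length
        if rng.random() < 0.05:
            pos = int(rng.integers(0, length))
            seq = seq[:pos] + "X" + seq[pos + 1:]
        if rng.random() < 0.03:
            pos = int(rng.integers(0, length))
            seq = seq[:pos] + "B" + seq[pos + 1:]
        resolved = int(rng.integers(0, length + 1))
        records.append(ChainRecord(
            chain_id=f"chain{i}",
            release_date=str(rng.choice(["2017-06-01", "2018-04-30", "2019-03-02", "2020-11-20"])),
            sequence=seq,
            resolved_count=resolved,
            resolved_ca=int(rng.integers(0, resolved + 1)),
            method=str(rng.choice(["XRAY", "XRAY", "EM", "NMR"])),
            resolution=float(np.round(rng.uniform(1.0, 4.5), 2)),
            cluster_id=int(rng.integers(0, max(2, n // 3))),
        ))
    # guaranteed boundary cases
    base = dict(release_date="2019-01-01", method="XRAY", resolution=2.0)
    records.append(ChainRecord("edge15", sequence="".join(rng.choice(aa, 40)),
                               resolved_count=15, resolved_ca=15, cluster_id=9001, **base))
    records.append(ChainRecord("edge1401", sequence="".join(rng.choice(aa, 1401)),
                               resolved_count=1200, resolved_ca=1200, cluster_id=9002, **base))
    dup_seq = "".join(rng.choice(aa, 120))
    records.append(ChainRecord("dupA", sequence=dup_seq, resolved_count=110,
                               resolved_ca=90, cluster_id=9003, **base))
    records.append(ChainRecord("dupB", sequence=dup_seq, resolved_count=115,
                               resolved_ca=110, cluster_id=9003, **base))
    return records
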
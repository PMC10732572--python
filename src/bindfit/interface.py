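"""Protein-protein/peptide interface analysis from atomic coordinates.

Given a structure and two disjoint chain selections this module counts
inter-selection atomic contacts under a distance cutoff (4.2 A by default,
heavy atoms only, waters and ions excluded), identifies hydrogen bonds from
a donor/acceptor dictionary (distance criterion, plus a D-H...A angle test
when explicit hydrogens are present), attributes per-residue contact shares,
and estimates the buried solvent-accessible surface area by sphere-point
(Shrake-Rupley style) quadrature::

    buried = (SASA_A + SASA_B - SASA_AB) / 2

PDB reading and writing go through gemmi; the in-memory representation is a
flat atom table so every geometric operation is plain numpy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Structure",
    "ContactSet",
    "InterfaceStats",
    "VDW_RADII",
    "read_structure",
    "write_structure",
    "count_contacts",
    "detect_hbonds",
    "buried_area",
    "contact_share",
    "interface_stats",
]

#: van der Waals radii in angstrom (Bondi 1964, with common ions appended).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39,
    "FE": 2.00, "MN": 2.00, "CU": 1.40,
}

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}
_ION_NAMES = {"NA", "K", "MG", "CA", "ZN", "CL", "MN", "FE", "CU", "BR", "IOD"}

# hydrogen-bond donor/acceptor heavy atoms for the 20 standard residues;
# backbone N donates and backbone O accepts for every residue
_SIDECHAIN_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASN": {"OD1"}, "ASP": {"OD1", "OD2"}, "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "MET": {"SD"}, "CYS": {"SG"},
}
_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass(frozen=True)
class Atom:
    chain: str
    res_seq: int
    icode: str
    res_name: str
    name: str
    element: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0
    hetero: bool = False

    @property
    def is_water(self) -> bool:
        return self.res_name in _WATER_NAMES

    @property
    def is_ion(self) -> bool:
        return self.hetero and self.res_name in _ION_NAMES

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain, self.res_seq, self.icode)


class Structure:
    """Flat atom list with cached coordinates and selection helpers."""

    def __init__(self, atoms: list[Atom], name: str = ""):
        if not atoms:
            raise ValueError("structure has no atoms")
        keys = [(a.chain, a.res_seq, a.icode, a.name) for a in atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, atom) keys")
        self.atoms = list(atoms)
        self.name = name
        self.coords = np.array([a.xyz for a in atoms], dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def select(
        self,
        chains,
        heavy_only: bool = True,
        exclude_water: bool = True,
        exclude_ions: bool = True,
    ) -> np.ndarray:
        """Indices of atoms in the given chain(s) under the census flags."""
        if isinstance(chains, str):
            chains = {chains}
        chains = set(chains)
        idx = []
        for i, a in enumerate(self.atoms):
            if a.chain not in chains:
                continue
            if heavy_only and a.element == "H":
                continue
            if exclude_water and a.is_water:
                continue
            if exclude_ions and a.is_ion:
                continue
            idx.append(i)
        return np.asarray(idx, dtype=int)

    def water_indices(self, oxygen_only: bool = True) -> np.ndarray:
        return np.asarray(
            [i for i, a in enumerate(self.atoms)
             if a.is_water and (not oxygen_only or a.element == "O")],
            dtype=int,
        )


@dataclass(frozen=True)
class ContactSet:
    """Inter-selection atom pairs within the cutoff distance."""

    pairs: list[tuple[int, int, float]]  # (index in A-sel, index in B-sel, A)
    cutoff: float
    structure: Structure
    selection_a: np.ndarray
    selection_b: np.ndarray

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)

    def residue_counts(self) -> dict[tuple[str, int, str], int]:
        """Contacts touching each residue (a pair counts for both sides)."""
        counts: dict[tuple[str, int, str], int] = {}
        for ia, ib, _ in self.pairs:
            for atom in (self.structure.atoms[ia], self.structure.atoms[ib]):
                counts[atom.residue_id] = counts.get(atom.residue_id, 0) + 1
        return counts


@dataclass
class HBond:
    donor: int  # atom index (heavy donor)
    acceptor: int
    distance: float
    water_mediated: bool = False
    bridge_water: int | None = None


@dataclass
class InterfaceStats:
    n_contacts: int
    n_hbonds: int
    buried_area: float  # A^2
    per_residue_counts: dict[tuple[str, int, str], int]
    per_residue_shares: dict[tuple[str, int, str], float]
    cutoff: float
    method: dict = field(default_factory=dict)


# ---------------------------------------------------------------- IO

def read_structure(path: str, keep_altloc: str = "highest-occupancy") -> Structure:
    """Read a PDB file into a Structure.

    Alternate locations are collapsed to the highest-occupancy conformer;
    residue numbering and insertion codes are preserved verbatim.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    atoms: list[Atom] = []
    best: dict[tuple, tuple[float, int]] = {}
    model = st[0]
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                key = (chain.name, res.seqid.num, res.seqid.icode.strip(),
                       at.name)
                rec = Atom(
                    chain=chain.name,
                    res_seq=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    res_name=res.name.strip(),
                    name=at.name,
                    element=at.element.name.upper() or _guess_element(at.name),
                    xyz=(at.pos.x, at.pos.y, at.pos.z),
                    occupancy=at.occ,
                    b_factor=at.b_iso,
                    hetero=het,
                )
                prev = best.get(key)
                if prev is None or at.occ > prev[0]:
                    if prev is not None:
                        atoms[prev[1]] = rec
                        best[key] = (at.occ, prev[1])
                        continue
                    best[key] = (at.occ, len(atoms))
                    atoms.append(rec)
    return Structure(atoms, name=st.name or str(path))


def write_structure(struct: Structure, path: str) -> None:
    """Write a Structure to PDB format (via gemmi)."""
    # gemmi containers copy on add_*, so build residues fully before nesting
    residues: dict[tuple, gemmi.Residue] = {}
    chain_order: dict[str, list[tuple]] = {}
    for a in struct.atoms:
        rkey = a.residue_id
        if rkey not in residues:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, a.icode or " ")
            res.het_flag = "H" if a.hetero else "A"
            residues[rkey] = res
            chain_order.setdefault(a.chain, []).append(rkey)
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element.capitalize())
        at.pos = gemmi.Position(*a.xyz)
        at.occ = a.occupancy
        at.b_iso = a.b_factor
        residues[rkey].add_atom(at)
    st = gemmi.Structure()
    st.name = struct.name or "bindfit"
    model = gemmi.Model("1")
    for chain_name, rkeys in chain_order.items():
        chain = gemmi.Chain(chain_name)
        for rkey in rkeys:
            chain.add_residue(residues[rkey])
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if stripped[:2].upper() in VDW_RADII and len(stripped) > 1:
        return stripped[:2].upper()
    return stripped[:1].upper()


# ---------------------------------------------------------------- contacts

def count_contacts(
    struct: Structure,
    selection_a,
    selection_b,
    cutoff: float = 4.2,
    heavy_only: bool = True,
    exclude_water: bool = True,
    exclude_ions: bool = True,
) -> ContactSet:
    """All inter-selection atom pairs within ``cutoff`` angstrom.

    Selections are chain labels (str or iterable) or explicit atom-index
    arrays; they must be disjoint.
    """
    idx_a = _resolve_selection(struct, selection_a, heavy_only,
                               exclude_water, exclude_ions)
    idx_b = _resolve_selection(struct, selection_b, heavy_only,
                               exclude_water, exclude_ions)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("empty selection")
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("selections must be disjoint")
    xa, xb = struct.coords[idx_a], struct.coords[idx_b]
    tree = cKDTree(xb)
    pairs: list[tuple[int, int, float]] = []
    for i, neighbors in enumerate(tree.query_ball_point(xa, cutoff)):
        for j in neighbors:
            d = float(np.linalg.norm(xa[i] - xb[j]))
            if d <= cutoff:
                pairs.append((int(idx_a[i]), int(idx_b[j]), d))
    return ContactSet(pairs, cutoff, struct, idx_a, idx_b)


def _resolve_selection(struct, selection, heavy_only, exclude_water,
                       exclude_ions) -> np.ndarray:
    if isinstance(selection, (str, set, list, tuple)) and all(
        isinstance(c, str) for c in
        ([selection] if isinstance(selection, str) else selection)
    ):
        return struct.select(selection, heavy_only=heavy_only,
                             exclude_water=exclude_water,
                             exclude_ions=exclude_ions)
    return np.asarray(selection, dtype=int)


# ---------------------------------------------------------------- H-bonds

def _donor_acceptor_indices(struct: Structure, idx: np.ndarray):
    donors, acceptors = [], []
    warned: set[str] = set()
    for i in idx:
        a = struct.atoms[i]
        if a.is_water or a.is_ion:
            continue
        if a.res_name not in _STANDARD_RESIDUES:
            if a.res_name not in warned:
                warnings.warn(
                    f"unknown residue {a.res_name}: skipped in H-bond typing",
                    stacklevel=3,
                )
                warned.add(a.res_name)
            continue
        if a.name == "N" and a.res_name != "PRO":
            donors.append(i)
        if a.name in ("O", "OXT"):
            acceptors.append(i)
        if a.name in _SIDECHAIN_DONORS.get(a.res_name, ()):
            donors.append(i)
        if a.name in _SIDECHAIN_ACCEPTORS.get(a.res_name, ()):
            acceptors.append(i)
    return np.asarray(donors, dtype=int), np.asarray(acceptors, dtype=int)


def _attached_hydrogens(struct: Structure, heavy_idx: int) -> list[int]:
    a = struct.atoms[heavy_idx]
    out = []
    for i, h in enumerate(struct.atoms):
        if h.element == "H" and h.residue_id == a.residue_id:
            if np.linalg.norm(struct.coords[i] - struct.coords[heavy_idx]) < 1.25:
                out.append(i)
    return out


def detect_hbonds(
    struct: Structure,
    selection_a,
    selection_b,
    d_max: float = 3.5,
    angle_min: float = 120.0,
    water_mediated: bool = False,
) -> list[HBond]:
    """Hydrogen bonds between two selections.

    Direct bonds pair a donor heavy atom on one side with an acceptor on the
    other at distance <= ``d_max``; when the donor carries explicit
    hydrogens, the D-H...A angle must exceed ``angle_min`` degrees (crystal
    structures without hydrogens fall back to distance-only).  With
    ``water_mediated=True``, A-water-B bridges (one water oxygen within
    ``d_max`` of a donor/acceptor on each side) are appended.
    """
    idx_a = _resolve_selection(struct, selection_a, False, True, True)
    idx_b = _resolve_selection(struct, selection_b, False, True, True)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("empty selection")
    bonds: list[HBond] = []
    seen: set[tuple[int, int]] = set()
    for don_idx, acc_idx in (
        _pairwise_da(struct, idx_a, idx_b),
        _pairwise_da(struct, idx_b, idx_a),
    ):
        for d_i, a_i in zip(don_idx, acc_idx):
            dist = float(np.linalg.norm(struct.coords[d_i] - struct.coords[a_i]))
            key = (min(d_i, a_i), max(d_i, a_i))
            if key in seen:
                continue
            hydrogens = _attached_hydrogens(struct, d_i)
            if hydrogens and not _angle_ok(struct, d_i, hydrogens, a_i, angle_min):
                continue
            seen.add(key)
            bonds.append(HBond(int(d_i), int(a_i), dist))
    if water_mediated:
        bonds.extend(_water_bridges(struct, idx_a, idx_b, d_max, seen))
    return bonds


def _pairwise_da(struct, idx_don_side, idx_acc_side, d_max: float = 3.5):
    donors, _ = _donor_acceptor_indices(struct, idx_don_side)
    _, acceptors = _donor_acceptor_indices(struct, idx_acc_side)
    if donors.size == 0 or acceptors.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    tree = cKDTree(struct.coords[acceptors])
    out_d, out_a = [], []
    for k, neighbors in enumerate(tree.query_ball_point(struct.coords[donors], d_max)):
        for j in neighbors:
            out_d.append(donors[k])
            out_a.append(acceptors[j])
    return np.asarray(out_d, dtype=int), np.asarray(out_a, dtype=int)


def _angle_ok(struct, donor, hydrogens, acceptor, angle_min) -> bool:
    for h in hydrogens:
        hv = struct.coords[h]
        v1 = struct.coords[donor] - hv
        v2 = struct.coords[acceptor] - hv
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle >= angle_min:
            return True
    return False


def _water_bridges(struct, idx_a, idx_b, d_max, seen_direct):
    waters = struct.water_indices()
    if waters.size == 0:
        return []
    polar_a = np.concatenate(_donor_acceptor_indices(struct, idx_a)) \
        if idx_a.size else np.array([], dtype=int)
    polar_b = np.concatenate(_donor_acceptor_indices(struct, idx_b)) \
        if idx_b.size else np.array([], dtype=int)
    polar_a, polar_b = np.unique(polar_a), np.unique(polar_b)
    if polar_a.size == 0 or polar_b.size == 0:
        return []
    bridges = []
    for w in waters:
        wx = struct.coords[w]
        da = np.linalg.norm(struct.coords[polar_a] - wx, axis=1)
        db = np.linalg.norm(struct.coords[polar_b] - wx, axis=1)
        if np.any(da <= d_max) and np.any(db <= d_max):
            ia = int(polar_a[np.argmin(da)])
            ib = int(polar_b[np.argmin(db)])
            bridges.append(HBond(ia, ib, float(np.min(da) + np.min(db)),
                                 water_mediated=True, bridge_water=int(w)))
    return bridges


# ---------------------------------------------------------------- SASA

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def _sasa(coords: np.ndarray, radii: np.ndarray, probe: float,
          n_points: int) -> float:
    """Total solvent-accessible surface area by sphere-point quadrature."""
    sphere = _fibonacci_sphere(n_points)
    r_ext = radii + probe
    tree = cKDTree(coords)
    total = 0.0
    r_max = float(np.max(r_ext))
    for i in range(coords.shape[0]):
        pts = coords[i] + r_ext[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], r_ext[i] + r_max)
                     if j != i]
        if neighbors:
            nb = np.asarray(neighbors, dtype=int)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = np.any(d2 < (r_ext[nb] ** 2)[None, :], axis=1)
            accessible = int(np.count_nonzero(~buried))
        else:
            accessible = n_points
        total += 4.0 * np.pi * r_ext[i] ** 2 * accessible / n_points
    return total


def _radii_for(struct: Structure, idx: np.ndarray) -> np.ndarray:
    radii = np.empty(idx.size)
    for k, i in enumerate(idx):
        el = struct.atoms[i].element
        if el not in VDW_RADII:
            raise KeyError(f"no van der Waals radius for element {el!r}")
        radii[k] = VDW_RADII[el]
    return radii


def buried_area(
    struct: Structure,
    chains_a,
    chains_b,
    probe: float = 1.4,
    n_points: int = 960,
    heavy_only: bool = True,
) -> float:
    """Interface area buried between two chain groups, in A^2.

    buried = (SASA_A + SASA_B - SASA_AB)/2, each SASA from Fibonacci
    sphere-point quadrature with ``n_points`` per atom and a ``probe``
    radius of 1.4 A (water).
    """
    idx_a = _resolve_selection(struct, chains_a, heavy_only, True, True)
    idx_b = _resolve_selection(struct, chains_b, heavy_only, True, True)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("empty selection")
    ra, rb = _radii_for(struct, idx_a), _radii_for(struct, idx_b)
    xa, xb = struct.coords[idx_a], struct.coords[idx_b]
    sasa_a = _sasa(xa, ra, probe, n_points)
    sasa_b = _sasa(xb, rb, probe, n_points)
    sasa_ab = _sasa(np.vstack([xa, xb]), np.concatenate([ra, rb]),
                    probe, n_points)
    return 0.5 * (sasa_a + sasa_b - sasa_ab)


def contact_share(contacts: ContactSet, residues) -> float:
    """Fraction of contacts touching any residue in ``residues``.

    ``residues`` is an iterable of (chain, res_seq) or
    (chain, res_seq, icode) tuples.
    """
    subset = {(r if len(r) == 3 else (r[0], r[1], "")) for r in residues}
    if contacts.n_contacts == 0:
        return 0.0
    known = {a.residue_id for a in contacts.structure.atoms}
    missing = subset - known
    if missing:
        raise KeyError(f"residues not in structure: {sorted(missing)}")
    hit = 0
    for ia, ib, _ in contacts.pairs:
        ra = contacts.structure.atoms[ia].residue_id
        rb = contacts.structure.atoms[ib].residue_id
        if ra in subset or rb in subset:
            hit += 1
    return hit / contacts.n_contacts


def interface_stats(
    struct: Structure,
    chains_a,
    chains_b,
    cutoff: float = 4.2,
    hbond_d_max: float = 3.5,
    probe: float = 1.4,
    n_points: int = 960,
    water_mediated_hbonds: bool = False,
) -> InterfaceStats:
    """One-call census: contacts, H-bonds, buried area, residue shares."""
    contacts = count_contacts(struct, chains_a, chains_b, cutoff=cutoff)
    hbonds = detect_hbonds(struct, chains_a, chains_b, d_max=hbond_d_max,
                           water_mediated=water_mediated_hbonds)
    area = buried_area(struct, chains_a, chains_b, probe=probe,
                       n_points=n_points)
    counts = contacts.residue_counts()
    total = sum(counts.values())
    shares = {k: v / total for k, v in counts.items()} if total else {}
    return InterfaceStats(
        contacts.n_contacts, len(hbonds), area, counts, shares, cutoff,
        method={
            "cutoff_A": cutoff, "heavy_only": True, "waters": "excluded",
            "ions": "excluded", "hbond_d_max_A": hbond_d_max,
            "probe_A": probe, "sasa_points": n_points,
            "hbond_criteria": "distance-only unless explicit H present",
        },
    )
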
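"""Coordinate-level measurements on RyR structures.

Implements the distance and displacement metrics used to compare channel
states across PDB/mmCIF structures:

* Calpha-Calpha distances between residue pairs at the EF-hand / S23*-loop
  interface (the D1 pair E4075-R4736* and D2 pair K4101-D4730* in rabbit
  RyR1 numbering);
* the maximum Calpha separation still compatible with a side-chain H-bond,
  d_D + d_A + 2.7 A, where d_D/d_A are the Calpha-to-farthest-O/N reaches
  of the donor (D/E) and acceptor (K/R) side chains in extended
  conformation and 2.7 A is the standard H-bond length;
* rigid Kabsch superposition on a reference domain (the Central domain by
  default) followed by length-normalized RMSD,
  RMSD100 = RMSD / (1 + ln sqrt(N/100)), with RMSD100 > 2 A taken as a
  significant conformational difference;
* the flexion angle of the cytosolic shell: the signed angle between the
  Calpha(348)-Calpha(1052) line and the plane perpendicular to the
  channel's four-fold axis (negative = tilted toward the membrane).

File I/O goes through gemmi; residue numbering follows the coordinate file
(author numbering).  Structures with insertion codes are rejected; for
alternate conformations the highest-occupancy altloc is kept.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "StructureFrame",
    "DOMAIN_RANGES",
    "CENTRAL_ALIGN_INTERVALS",
    "EXTENDED_REACH",
    "ca_distance",
    "max_interaction_distance",
    "align_on_domain",
    "RigidTransform",
    "rmsd100",
    "Rmsd100Result",
    "flexion_angle",
    "make_ca_chain",
    "make_tetramer",
    "apply_rigid",
    "extended_sidechain_reach",
]

RMSD100_SIGNIFICANCE = 2.0  # Angstrom
HBOND_LENGTH = 2.7          # Angstrom, standard donor-acceptor separation

#: Residue intervals of the core domains per isoform (author numbering).
DOMAIN_RANGES = {
    "rRyR1": {
        "CD":  [(3668, 4070)],
        "EF":  [(4071, 4131)],
        "U":   [(4132, 4251)],
        "S23": [(4663, 4786)],
        "S45": [(4821, 4834)],
        "S6":  [(4910, 4956)],
        "CTD": [(4957, 5033)],
    },
    "mRyR2": {
        "CD":  [(3634, 4024)],
        "EF":  [(4025, 4085)],
        "U":   [(4086, 4205)],
        "S23": [(4591, 4715)],
        "S45": [(4750, 4763)],
        "S6":  [(4839, 4885)],
        "CTD": [(4886, 4962)],
    },
    "hRyR2": {
        "CD":  [(3635, 4025)],
        "EF":  [(4026, 4086)],
        "U":   [(4087, 4206)],
        "S23": [(4592, 4716)],
        "S45": [(4751, 4764)],
        "S6":  [(4840, 4886)],
        "CTD": [(4887, 4963)],
    },
    "rRyR2": {  # also pRyR2
        "CD":  [(3636, 4026)],
        "EF":  [(4027, 4087)],
        "U":   [(4088, 4207)],
        "S23": [(4593, 4717)],
        "S45": [(4752, 4765)],
        "S6":  [(4841, 4887)],
        "CTD": [(4888, 4964)],
    },
}

#: Central-domain sub-intervals resolved in all structures (rRyR1 numbering),
#: the default alignment reference for RMSD100 comparisons.
CENTRAL_ALIGN_INTERVALS = [(3668, 3679), (3694, 3733), (3753, 3855), (3873, 4070)]


class ResidueLookupError(KeyError):
    """A requested residue or its Calpha atom is absent from the frame."""


class StructureFrame:
    """A structure with unique (chain, residue, atom) coordinates.

    Thin wrapper over ``gemmi.Structure`` providing Calpha lookups and the
    altloc/insertion-code policy stated in the module docstring.
    """

    def __init__(self, structure: gemmi.Structure, source_id: str = ""):
        self.structure = structure
        self.source_id = source_id or structure.name
        self._prune_altlocs()
        self._index = self._build_index()

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_file(cls, path) -> "StructureFrame":
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        return cls(st, source_id=str(path))

    @classmethod
    def from_atoms(cls, records, source_id: str = "toy") -> "StructureFrame":
        """Build from an iterable of (chain, resnum, resname, atomname, x, y, z)."""
        st = gemmi.Structure()
        st.name = source_id
        model = gemmi.Model("1")
        chains: dict = {}
        for chain_name, resnum, resname, atomname, x, y, z in records:
            ch = chains.get(chain_name)
            if ch is None:
                ch = gemmi.Chain(chain_name)
                chains[chain_name] = ch
            res = None
            if len(ch) and ch[-1].seqid.num == resnum and ch[-1].name == resname:
                res = ch[-1]
            else:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(int(resnum), " ")
                ch.add_residue(res)
                res = ch[-1]
            atom = gemmi.Atom()
            atom.name = atomname
            atom.element = gemmi.Element(atomname[:1])
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            atom.occ = 1.0
            res.add_atom(atom)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
        st.setup_entities()
        return cls(st, source_id=source_id)

    # -- policy -------------------------------------------------------------
    def _prune_altlocs(self) -> None:
        model = self.structure[0]
        for chain in model:
            for res in chain:
                if res.seqid.icode not in (" ", "", "\x00"):
                    raise ValueError(
                        f"insertion code {res.seqid.icode!r} at {chain.name}:{res.seqid.num} "
                        "is not supported; renumber the structure first"
                    )
                by_name: dict = {}
                for atom in res:
                    prev = by_name.get(atom.name)
                    if prev is None or atom.occ > prev.occ:
                        by_name[atom.name] = atom
                keep = {id(a) for a in by_name.values()}
                for i in range(len(res) - 1, -1, -1):
                    if id(res[i]) not in keep:
                        del res[i]
                for atom in res:
                    atom.altloc = "\x00"

    def _build_index(self) -> dict:
        idx = {}
        for chain in self.structure[0]:
            for res in chain:
                for atom in res:
                    key = (chain.name, res.seqid.num, atom.name)
                    if key in idx:
                        raise ValueError(f"duplicate atom record {key}")
                    p = atom.pos
                    if not all(map(math.isfinite, (p.x, p.y, p.z))):
                        raise ValueError(f"non-finite coordinates at {key}")
                    idx[key] = np.array([p.x, p.y, p.z])
        return idx

    # -- queries ------------------------------------------------------------
    @property
    def chain_names(self):
        return [c.name for c in self.structure[0]]

    def ca(self, chain: str, resnum: int) -> np.ndarray:
        key = (chain, int(resnum), "CA")
        try:
            return self._index[key]
        except KeyError:
            raise ResidueLookupError(
                f"no Calpha for residue {chain}:{resnum} in {self.source_id}"
            ) from None

    def ca_in_intervals(self, chain: str, intervals) -> dict:
        """resnum -> Calpha position for residues present inside the intervals."""
        out = {}
        for lo, hi in intervals:
            for resnum in range(int(lo), int(hi) + 1):
                key = (chain, resnum, "CA")
                if key in self._index:
                    out[resnum] = self._index[key]
        return out

    def chain_centroid(self, chain: str) -> np.ndarray:
        pts = [v for (c, _, _), v in self._index.items() if c == chain]
        if not pts:
            raise ResidueLookupError(f"chain {chain!r} has no atoms")
        return np.mean(pts, axis=0)

    # -- output -------------------------------------------------------------
    def write_pdb(self, path) -> None:
        self.structure.write_pdb(str(path))

    def write_mmcif(self, path) -> None:
        self.structure.make_mmcif_document().write_file(str(path))


# --------------------------------------------------------------------------
# distances

def ca_distance(frame: StructureFrame, sel_a, sel_b) -> float:
    """Euclidean Calpha-Calpha distance in Angstrom; selections (chain, resnum)."""
    a = frame.ca(*sel_a)
    b = frame.ca(*sel_b)
    return float(np.linalg.norm(a - b))


# Idealized extended side-chain internal coordinates: (bond length A,
# bond angle deg at the previous atom), from CA to the farthest O/N.
# sp3-sp3 bonds 1.52-1.53 A at tetrahedral 111 deg; carboxylate C-O 1.25 A
# and guanidinium C-N 1.33 A branch at 120 deg (sp2).
_SIDECHAIN_ZMAT = {
    "ASP": [(1.53, None), (1.52, 111.0), (1.25, 120.0)],                     # CB CG OD
    "GLU": [(1.53, None), (1.52, 111.0), (1.52, 111.0), (1.25, 120.0)],      # CB CG CD OE
    "LYS": [(1.53, None), (1.52, 111.0), (1.52, 111.0), (1.52, 111.0),
            (1.49, 111.0)],                                                  # CB..CE NZ
    "ARG": [(1.53, None), (1.52, 111.0), (1.52, 111.0), (1.46, 111.0),
            (1.33, 120.0), (1.33, 120.0)],                                   # CB..NE CZ NH
}
_ONE_TO_THREE = {"D": "ASP", "E": "GLU", "K": "LYS", "R": "ARG"}


def _zigzag_positions(zmat):
    """Planar all-trans chain from internal coordinates, CA at the origin."""
    pts = [np.zeros(2)]
    heading = 0.0
    for i, (length, angle) in enumerate(zmat):
        if angle is not None:
            turn = math.radians(180.0 - angle)
            heading += turn if i % 2 else -turn
        pts.append(pts[-1] + length * np.array([math.cos(heading), math.sin(heading)]))
    return np.array(pts)


def extended_sidechain_reach(restype: str) -> float:
    """Calpha-to-farthest-O/N distance (A) of an idealized extended side chain."""
    name = _ONE_TO_THREE.get(restype.upper(), restype.upper())
    if name not in _SIDECHAIN_ZMAT:
        raise ValueError(
            f"unsupported residue {restype!r}; donors are D/E, acceptors K/R"
        )
    pts = _zigzag_positions(_SIDECHAIN_ZMAT[name])
    return float(np.linalg.norm(pts[-1] - pts[0]))


#: Shipped reach values (A), evaluated once from the idealized geometries.
EXTENDED_REACH = {code: extended_sidechain_reach(code) for code in "DEKR"}

_DONORS = frozenset("DE")
_ACCEPTORS = frozenset("KR")


def max_interaction_distance(donor: str, acceptor: str, reach: dict | None = None) -> float:
    """Maximum Calpha separation allowing a donor-acceptor H-bond: d_D + d_A + 2.7 A.

    Arguments are one-letter residue types; the donor must be D/E and the
    acceptor K/R, in either argument order (the sum is symmetric).
    """
    reach = reach or EXTENDED_REACH
    a, b = donor.upper(), acceptor.upper()
    if a in _ACCEPTORS and b in _DONORS:
        a, b = b, a
    if a not in _DONORS or b not in _ACCEPTORS:
        raise ValueError(
            f"unsupported donor/acceptor pair {donor!r}/{acceptor!r}; need one of D/E with one of K/R"
        )
    return reach[a] + reach[b] + HBOND_LENGTH


# --------------------------------------------------------------------------
# superposition and RMSD100

@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray     # 3x3 proper rotation
    translation: np.ndarray  # applied after rotation

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def _paired_cas(frame, reference, intervals, chain, ref_chain):
    mob = frame.ca_in_intervals(chain, intervals)
    ref = reference.ca_in_intervals(ref_chain, intervals)
    common = sorted(set(mob) & set(ref))
    return common, mob, ref


def align_on_domain(frame: StructureFrame, reference: StructureFrame, intervals,
                    chain: str | None = None, ref_chain: str | None = None):
    """Least-squares rigid superposition of interval Calphas onto the reference.

    Pairs Calpha atoms by residue number inside ``intervals`` and returns
    ``(RigidTransform, paired residue numbers)``.  The rotation is always
    proper (det = +1, Kabsch).
    """
    chain = chain or frame.chain_names[0]
    ref_chain = ref_chain or reference.chain_names[0]
    common, mob, ref = _paired_cas(frame, reference, intervals, chain, ref_chain)
    if len(common) < 3:
        missing = [iv for iv in intervals]
        raise ValueError(
            f"only {len(common)} common Calpha atoms in {missing}; "
            "need at least 3 for superposition"
        )
    x = np.array([mob[r] for r in common])
    y = np.array([ref[r] for r in common])
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    rot, _ = Rotation.align_vectors(y - yc, x - xc)
    rmat = rot.as_matrix()
    transform = RigidTransform(rotation=rmat, translation=yc - rmat @ xc)
    return transform, common


@dataclass(frozen=True)
class Rmsd100Result:
    rmsd: float
    rmsd100: float
    n_residues: int
    significant: bool


def rmsd100(frame: StructureFrame, reference: StructureFrame, domain,
            alignment_domain=None, chain: str | None = None,
            ref_chain: str | None = None) -> Rmsd100Result:
    """Length-normalized Calpha RMSD of ``domain`` after aligning elsewhere.

    The structures are first superposed on ``alignment_domain`` (default:
    the Central-domain intervals), never on the measured domain itself, so
    the metric reports displacement of the domain relative to the aligned
    reference frame.  RMSD100 = RMSD / (1 + ln sqrt(N/100)); values above
    2 A flag a significant conformational change.  The normalization
    diverges as N approaches ~14 residues, where the formula loses
    validity; short segments raise or warn accordingly.
    """
    chain = chain or frame.chain_names[0]
    ref_chain = ref_chain or reference.chain_names[0]
    alignment_domain = alignment_domain if alignment_domain is not None else CENTRAL_ALIGN_INTERVALS
    transform, _ = align_on_domain(frame, reference, alignment_domain, chain, ref_chain)

    common, mob, ref = _paired_cas(frame, reference, domain, chain, ref_chain)
    n = len(common)
    if n < 2:
        raise ValueError(f"need at least 2 paired residues in the measured domain, got {n}")
    factor = 1.0 + math.log(math.sqrt(n / 100.0))
    if factor <= 0.1:
        raise ValueError(
            f"domain of {n} residues is too short for RMSD100 normalization "
            f"(factor {factor:.3f}); report the raw RMSD instead"
        )
    if n < 20:
        warnings.warn(
            f"RMSD100 normalization is unreliable for short domains (N={n})",
            stacklevel=2,
        )
    x = transform.apply(np.array([mob[r] for r in common]))
    y = np.array([ref[r] for r in common])
    rmsd = float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))
    r100 = rmsd / factor
    return Rmsd100Result(rmsd=rmsd, rmsd100=r100, n_residues=n,
                         significant=r100 > RMSD100_SIGNIFICANCE)


# --------------------------------------------------------------------------
# flexion angle

def estimate_symmetry_axis(frame: StructureFrame) -> np.ndarray:
    """Unit normal of the best-fit plane through the chain centroids.

    Requires at least 3 chains (the tetramer's four in practice); the sign
    is fixed deterministically to a non-negative z component.  Pass an
    explicit axis to :func:`flexion_angle` for fragments without usable
    symmetry.
    """
    names = frame.chain_names
    if len(names) < 3:
        raise ValueError(
            f"cannot estimate the symmetry axis from {len(names)} chain(s); "
            "supply axis= explicitly"
        )
    cents = np.array([frame.chain_centroid(c) for c in names])
    centered = cents - cents.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-8:  # centroids collinear
        raise ValueError("chain centroids are collinear; supply axis= explicitly")
    normal = vt[-1]
    if normal[2] < 0 or (normal[2] == 0 and (normal[0] < 0 or (normal[0] == 0 and normal[1] < 0))):
        normal = -normal
    return normal / np.linalg.norm(normal)


def flexion_angle(frame: StructureFrame, residue_pair=(348, 1052),
                  chain: str | None = None, axis=None) -> float:
    """Signed angle (deg) between the reference Calpha line and the horizontal plane.

    The horizontal plane is the plane perpendicular to the channel's
    four-fold axis (estimated from the chain centroids unless ``axis`` is
    given).  Negative values mean the line from residue ``pair[0]`` to
    ``pair[1]`` points against the axis direction, i.e. downward toward the
    membrane for an axis oriented cytosolic-side up.
    """
    chain = chain or frame.chain_names[0]
    axis = np.asarray(axis, dtype=float) if axis is not None else estimate_symmetry_axis(frame)
    axis = axis / np.linalg.norm(axis)
    a = frame.ca(chain, residue_pair[0])
    b = frame.ca(chain, residue_pair[1])
    u = b - a
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("reference residues coincide; flexion angle undefined")
    return float(np.degrees(np.arcsin(np.clip(np.dot(u / norm, axis), -1.0, 1.0))))


# --------------------------------------------------------------------------
# toy structure generation (test fixtures and worked examples)

def make_ca_chain(n_res: int, chain: str = "A", start: int = 1,
                  resname: str = "ALA", rise: float = 1.5,
                  radius: float = 2.3, twist_deg: float = 100.0):
    """Idealized alpha-helical Calpha trace as atom records."""
    records = []
    for i in range(n_res):
        ang = math.radians(twist_deg * i)
        records.append((chain, start + i, resname, "CA",
                        radius * math.cos(ang), radius * math.sin(ang), rise * i))
    return records


def make_tetramer(tilt_deg: float = 0.0, line_length: float = 30.0,
                  radius: float = 60.0, body_radius: float = 40.0,
                  residue_pair=(348, 1052)) -> StructureFrame:
    """Synthetic four-fold symmetric tetramer with a known flexion angle.

    Each chain carries a short body (residues 100-119, defining the chain
    centroid) and the two reference residues of ``residue_pair`` whose
    Calpha line is tilted by ``tilt_deg`` out of the plane perpendicular to
    the z axis.  Chains B-D are 90/180/270-degree copies of chain A about
    z, so the estimated symmetry axis is +z by construction.
    """
    tilt = math.radians(tilt_deg)
    base = []
    for i, (c, r, n, a, x, y, z) in enumerate(make_ca_chain(20, "A", start=100)):
        base.append((c, r, n, a, x + body_radius, y, z))
    p1 = np.array([radius, 0.0, 0.0])
    u = np.array([math.cos(tilt), 0.0, math.sin(tilt)])
    p2 = p1 + line_length * u
    base.append(("A", residue_pair[0], "GLY", "CA", *p1))
    base.append(("A", residue_pair[1], "GLY", "CA", *p2))

    records = []
    for k, chain in enumerate("ABCD"):
        ang = math.radians(90.0 * k)
        ca, sa = math.cos(ang), math.sin(ang)
        for (_, resnum, resname, atomname, x, y, z) in base:
            records.append((chain, resnum, resname, atomname,
                            ca * x - sa * y, sa * x + ca * y, z))
    return StructureFrame.from_atoms(records, source_id=f"synthetic-tetramer-tilt{tilt_deg:g}")


def apply_rigid(frame: StructureFrame, rotation=None, translation=(0.0, 0.0, 0.0),
                source_id: str | None = None) -> StructureFrame:
    """Copy of ``frame`` with a rigid motion applied to every atom."""
    rmat = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    records = []
    for chain in frame.structure[0]:
        for res in chain:
            for atom in res:
                p = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                q = rmat @ p + t
                records.append((chain.name, res.seqid.num, res.name, atom.name, *q))
    return StructureFrame.from_atoms(
        records, source_id=source_id or f"{frame.source_id}+rigid"
    )
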
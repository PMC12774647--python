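"""Synthetic structure, table and distribution generators.

Everything the test suite and the packaged reference data need is built
here from internal coordinates — no downloads. The central operation,
:func:`build_oligonucleotide`, grows a heavy-atom nucleic-acid chain by
sequential NeRF placement from ideal bond lengths/angles (packaged in
``data/ideal_geometry.csv``) and caller-supplied backbone/glycosidic
torsions, so that re-measuring a built fragment recovers the requested
step parameters exactly (at zero noise).

The module also generates:

* seeded synthetic reference distributions for valence-geometry terms
  (emulating empirical bond/angle samples from a curated reference set),
* well-separated synthetic NtC class tables, including the packaged
  96-class / 14-CANA-code table. The packaged table is self-consistent
  but synthetic: its numeric values come from the documented
  canonical-form torsion grid below, not from any published class table.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .geometry import place_atom, wrap_angle
from .model import Atom, Chain, Model, Residue, Structure
from .steps import DinucleotideStep, StepParameters, compute_step_parameters, find_steps

__all__ = [
    "FragmentSpec",
    "build_oligonucleotide",
    "build_step_from_torsions",
    "make_reference_distribution",
    "make_test_table",
    "make_reference_table",
    "write_table_csv",
    "CANA_CODES",
    "FAMILY_SIZES",
]

_RNA_COMPS = {"A": "A", "C": "C", "G": "G", "U": "U"}
_DNA_COMPS = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}

_ELEMENT = {"P": "P"}


def _element_of(name: str) -> str:
    return _ELEMENT.get(name, name[0])


def _load_ideal() -> dict[tuple[str, str], float]:
    table = {}
    with resources.files("ntckit.data").joinpath("ideal_geometry.csv").open() as fh:
        for row in csv.DictReader(fh):
            table[(row["kind"], row["name"])] = float(row["value"])
    return table


_IDEAL = _load_ideal()


def _b(name: str) -> float:
    return _IDEAL[("bond", name)]


def _a(name: str) -> float:
    return _IDEAL[("angle", name)]


def _t(name: str) -> float:
    return _IDEAL[("torsion", name)]


@dataclass
class FragmentSpec:
    """Recipe for a synthetic oligonucleotide.

    ``step_params`` holds one 12-parameter vector per dinucleotide step
    (len(sequence) - 1 of them). Where consecutive steps both constrain
    a shared residue's delta/chi, the 5'-side step wins: residue 0 takes
    d1/ch1 of step 0 and residue i >= 1 takes d2/ch2 of step i-1.
    ``torsion_noise`` (degrees) perturbs every placed backbone/glycosidic
    torsion; ``coord_noise`` (angstroms) perturbs final coordinates.
    Both are seeded and reproducible.
    """

    sequence: str
    step_params: list[StepParameters]
    is_dna: bool = False
    torsion_noise: float = 0.0
    coord_noise: float = 0.0
    seed: int = 0
    chain_id: str = "A"
    entry_id: str = "SYNT"
    gamma_first: float = field(default_factory=lambda: _t("seed_gamma"))

    def __post_init__(self) -> None:
        comps = _DNA_COMPS if self.is_dna else _RNA_COMPS
        bad = [b for b in self.sequence if b not in comps]
        if bad:
            raise ValueError(f"invalid base letter(s) {bad} for {'DNA' if self.is_dna else 'RNA'}")
        if len(self.step_params) != len(self.sequence) - 1:
            raise ValueError("sequence length must equal step count + 1")
        if self.torsion_noise < 0 or self.coord_noise < 0:
            raise ValueError("noise sigmas must be non-negative")


def _build_base(atoms: dict[str, np.ndarray], parent: str, chi: float) -> None:
    """Attach an idealized planar base to the sugar via the chi torsion."""
    o4, c1, = atoms["O4'"], atoms["C1'"]
    purine = parent in ("A", "G", "DA", "DG")
    n = atoms["N9" if purine else "N1"]
    if purine:
        atoms["C4"] = place_atom(o4, c1, n, _b("N9-C4"), _a("C1'-N9-C4"), chi)
        atoms["C5"] = place_atom(c1, n, atoms["C4"], _b("C4-C5"), _a("N9-C4-C5"), 180.0)
        atoms["N7"] = place_atom(n, atoms["C4"], atoms["C5"], _b("C5-N7"), _a("C4-C5-N7"), 0.0)
        atoms["C8"] = place_atom(atoms["C4"], atoms["C5"], atoms["N7"], _b("N7-C8"), _a("C5-N7-C8"), 0.0)
        atoms["N3"] = place_atom(atoms["N7"], atoms["C5"], atoms["C4"], _b("C4-N3"), _a("C5-C4-N3"), 180.0)
        atoms["C2"] = place_atom(atoms["C5"], atoms["C4"], atoms["N3"], _b("N3-C2"), _a("C4-N3-C2"), 0.0)
        atoms["N1"] = place_atom(atoms["C4"], atoms["N3"], atoms["C2"], _b("C2-N1"), _a("N3-C2-N1"), 0.0)
        atoms["C6"] = place_atom(atoms["N3"], atoms["C2"], atoms["N1"], _b("N1-C6"), _a("C2-N1-C6"), 0.0)
        if parent in ("A", "DA"):
            atoms["N6"] = place_atom(atoms["C2"], atoms["N1"], atoms["C6"], _b("C6-N6"), _a("N1-C6-N6"), 180.0)
        else:
            atoms["O6"] = place_atom(atoms["C2"], atoms["N1"], atoms["C6"], _b("C6-O6"), _a("N1-C6-O6"), 180.0)
            atoms["N2"] = place_atom(atoms["C4"], atoms["N3"], atoms["C2"], _b("C2-N2"), _a("N3-C2-N2"), 180.0)
    else:
        atoms["C2"] = place_atom(o4, c1, n, _b("N1-C2"), _a("C1'-N1-C2"), chi)
        atoms["N3"] = place_atom(c1, n, atoms["C2"], _b("C2-N3"), _a("N1-C2-N3"), 180.0)
        atoms["O2"] = place_atom(c1, n, atoms["C2"], _b("C2-O2"), _a("N1-C2-O2"), 0.0)
        atoms["C4"] = place_atom(n, atoms["C2"], atoms["N3"], _b("N3-C4"), _a("C2-N3-C4"), 0.0)
        atoms["C5"] = place_atom(atoms["C2"], atoms["N3"], atoms["C4"], _b("C4-C5pyr"), _a("N3-C4-C5pyr"), 0.0)
        atoms["C6"] = place_atom(atoms["N3"], atoms["C4"], atoms["C5"], _b("C5-C6"), _a("C4-C5-C6"), 0.0)
        if parent in ("U", "DT", "DU"):
            atoms["O4"] = place_atom(atoms["C2"], atoms["N3"], atoms["C4"], _b("C4-O4"), _a("N3-C4-O4"), 180.0)
        else:
            atoms["N4"] = place_atom(atoms["C2"], atoms["N3"], atoms["C4"], _b("C4-N4"), _a("N3-C4-N4"), 180.0)
        if parent == "DT":
            atoms["C7"] = place_atom(atoms["N3"], atoms["C4"], atoms["C5"], _b("C5-C7"), _a("C4-C5-C7"), 180.0)


def build_oligonucleotide(spec: FragmentSpec) -> Structure:
    """Build a heavy-atom oligonucleotide from internal coordinates.

    At zero noise, :func:`~ntckit.steps.compute_step_parameters` on the
    result recovers ``spec.step_params`` to 1e-6 for every parameter that
    the requested torsions determine (all nine torsions always; NN/CC/mu
    exactly when the requested vector is itself template-consistent, as
    all packaged class means are).
    """
    rng = np.random.default_rng(spec.seed)

    def jitter(angle: float) -> float:
        if spec.torsion_noise > 0:
            angle = angle + rng.normal(0.0, spec.torsion_noise)
        return wrap_angle(angle)

    comps = _DNA_COMPS if spec.is_dna else _RNA_COMPS
    residues: list[dict[str, np.ndarray]] = []
    prev: dict[str, np.ndarray] | None = None

    for i, base in enumerate(spec.sequence):
        parent = comps[base]
        purine = parent in ("A", "DA", "G", "DG")
        atoms: dict[str, np.ndarray] = {}
        if i == 0:
            sp = spec.step_params[0]
            delta, chi = sp.d1, sp.ch1
            gamma = spec.gamma_first
            atoms["O5'"] = np.zeros(3)
            atoms["C5'"] = np.array([_b("O5'-C5'"), 0.0, 0.0])
            dummy = np.array([0.0, 0.0, 1.0])
            atoms["C4'"] = place_atom(dummy, atoms["O5'"], atoms["C5'"], _b("C5'-C4'"), _a("O5'-C5'-C4'"), 60.0)
        else:
            sp = spec.step_params[i - 1]
            delta, chi = sp.d2, sp.ch2
            gamma = sp.g2
            atoms["P"] = place_atom(prev["C4'"], prev["C3'"], prev["O3'"], _b("O3'-P"), _a("C3'-O3'-P"), jitter(sp.e1))
            zeta = jitter(sp.z1)
            atoms["O5'"] = place_atom(prev["C3'"], prev["O3'"], atoms["P"], _b("P-O5'"), _a("O3'-P-O5'"), zeta)
            atoms["OP1"] = place_atom(prev["C3'"], prev["O3'"], atoms["P"], _b("P-OP1"), _a("O3'-P-OP1"), zeta + _t("op1_offset"))
            atoms["OP2"] = place_atom(prev["C3'"], prev["O3'"], atoms["P"], _b("P-OP2"), _a("O3'-P-OP2"), zeta + _t("op2_offset"))
            atoms["C5'"] = place_atom(prev["O3'"], atoms["P"], atoms["O5'"], _b("O5'-C5'"), _a("P-O5'-C5'"), jitter(sp.a2))
            atoms["C4'"] = place_atom(atoms["P"], atoms["O5'"], atoms["C5'"], _b("C5'-C4'"), _a("O5'-C5'-C4'"), jitter(sp.b2))
        gamma_n = jitter(gamma)
        atoms["C3'"] = place_atom(atoms["O5'"], atoms["C5'"], atoms["C4'"], _b("C4'-C3'"), _a("C5'-C4'-C3'"), gamma_n)
        atoms["O3'"] = place_atom(atoms["C5'"], atoms["C4'"], atoms["C3'"], _b("C3'-O3'"), _a("C4'-C3'-O3'"), jitter(delta))
        atoms["O4'"] = place_atom(atoms["O5'"], atoms["C5'"], atoms["C4'"], _b("C4'-O4'"), _a("C5'-C4'-O4'"), gamma_n + _t("ring_o4_offset"))
        atoms["C1'"] = place_atom(atoms["C5'"], atoms["C4'"], atoms["O4'"], _b("O4'-C1'"), _a("C4'-O4'-C1'"), _t("ring_c1"))
        atoms["C2'"] = place_atom(atoms["C4'"], atoms["O4'"], atoms["C1'"], _b("C1'-C2'"), _a("O4'-C1'-C2'"), _t("ring_c2"))
        if not spec.is_dna:
            atoms["O2'"] = place_atom(atoms["O4'"], atoms["C1'"], atoms["C2'"], _b("C2'-O2'"), _a("C1'-C2'-O2'"), _t("ring_o2"))
        n_name = "N9" if purine else "N1"
        atoms[n_name] = place_atom(atoms["C4'"], atoms["O4'"], atoms["C1'"], _b("C1'-N"), _a("O4'-C1'-N"), _t("ring_c2") + _t("glyco_offset"))
        _build_base(atoms, parent, jitter(chi))
        residues.append(atoms)
        prev = atoms

    if spec.coord_noise > 0:
        for atoms in residues:
            for name in atoms:
                atoms[name] = atoms[name] + rng.normal(0.0, spec.coord_noise, size=3)

    chain = Chain(chain_id=spec.chain_id)
    for i, (base, atoms) in enumerate(zip(spec.sequence, residues), start=1):
        res = Residue(chain_id=spec.chain_id, seq_id=str(i), comp_id=comps[base])
        for name, pos in atoms.items():
            res.atoms.append(Atom(name=name, element=_element_of(name), position=pos))
        chain.residues.append(res)
    return Structure(entry_id=spec.entry_id, models=[Model(num=1, chains=[chain])], source_format="synthetic")


def build_step_from_torsions(
    torsions: dict[str, float], sequence: str = "AA", is_dna: bool = False, seed: int = 0,
    torsion_noise: float = 0.0,
) -> tuple[Structure, DinucleotideStep, StepParameters]:
    """Build a single dinucleotide from the nine named torsions.

    ``torsions`` must carry d1 e1 z1 a2 b2 g2 d2 ch1 ch2 (degrees);
    NN/CC/mu emerge from the sugar/base template. Returns the structure,
    the detected step and its measured 12-parameter descriptor.
    """
    vec = [torsions[k] for k in StepParameters.TORSION_NAMES]
    params = StepParameters.from_vector(np.array(vec + [5.0, 5.0, 0.0]))  # nn/cc/mu placeholders
    spec = FragmentSpec(sequence=sequence, step_params=[params], is_dna=is_dna,
                        seed=seed, torsion_noise=torsion_noise)
    structure = build_oligonucleotide(spec)
    steps = find_steps(structure.models[0].chains[0])
    if len(steps) != 1:
        raise RuntimeError("dinucleotide build did not yield exactly one step")
    return structure, steps[0], compute_step_parameters(steps[0])


# ---------------------------------------------------------------------------
# synthetic reference distributions (valence geometry)
# ---------------------------------------------------------------------------

def make_reference_distribution(
    term_name: str,
    shape: str = "normal",
    params: dict | None = None,
    n: int = 200,
    seed: int = 0,
    csd_mean: float | None = None,
    csd_sigma: float | None = None,
):
    """Seeded synthetic empirical distribution for one bond/angle term.

    ``shape="normal"`` draws from N(loc, scale); ``shape="mixture"``
    from a two-component normal mixture (params: loc1, scale1, loc2,
    scale2, w1). CSD-style mean/sigma are settable independently of the
    sample so Preferred-union behaviour can be exercised. Case ids are
    synthetic ("SYN00001", ...).
    """
    from .valgeom import ReferenceDistribution  # local import to avoid a cycle

    if n < 20:
        raise ValueError("reference distribution needs n >= 20")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if shape == "normal":
        loc = params.get("loc", 0.0)
        scale = params.get("scale", 1.0)
        sample = rng.normal(loc, scale, size=n)
    elif shape == "mixture":
        w1 = params.get("w1", 0.5)
        k = rng.random(n) < w1
        sample = np.where(
            k,
            rng.normal(params.get("loc1", 0.0), params.get("scale1", 1.0), size=n),
            rng.normal(params.get("loc2", 3.0), params.get("scale2", 1.0), size=n),
        )
    else:
        raise ValueError(f"unknown shape {shape!r}")
    order = np.argsort(sample)
    sample = sample[order]
    case_ids = [f"SYN{i + 1:05d}" for i in range(n)]
    if csd_mean is None:
        csd_mean = float(np.mean(sample))
    if csd_sigma is None:
        csd_sigma = float(np.std(sample)) or 1.0
    return ReferenceDistribution(
        term_name=term_name,
        sample=np.asarray(sample, dtype=float),
        case_ids=case_ids,
        csd_mean=float(csd_mean),
        csd_sigma=float(csd_sigma),
        provenance=f"synthetic:{shape}:seed={seed}",
    )


# ---------------------------------------------------------------------------
# synthetic NtC class tables
# ---------------------------------------------------------------------------

#: the 14 CANA conformer codes (NAN is the extra not-assigned code)
CANA_CODES = (
    "AAA", "AAw", "AAu", "A-B", "B-A", "BBB", "BBw",
    "B12", "BB2", "miB", "ICL", "OPN", "SYN", "ZZZ",
)

#: class-name prefix and member count per CANA family; sums to 96
FAMILY_SIZES = (
    ("AA", "AAA", 10), ("AW", "AAw", 6), ("AU", "AAu", 4),
    ("AB", "A-B", 7), ("BA", "B-A", 7), ("BB", "BBB", 12),
    ("BW", "BBw", 6), ("B1", "B12", 6), ("B2", "BB2", 6),
    ("MB", "miB", 6), ("IC", "ICL", 6), ("OP", "OPN", 8),
    ("SY", "SYN", 6), ("ZZ", "ZZZ", 6),
)

#: shared sugar/glycosidic canonical-form torsions (degrees)
_DELTA_CANON = 84.0
_CHI_CANON = -160.0

#: grid of linkage-torsion values; 60-degree spacing guarantees that any
#: two distinct grid points differ by >= 60 degrees (wrapped) in at least
#: one coordinate, i.e. >= 6 tolerance units at the 10-degree tolerance
_GRID = (-150.0, -90.0, -30.0, 30.0, 90.0, 150.0)

#: default per-parameter tolerances (degrees / angstroms)
_DEFAULT_TOL = {
    "d1": 15.0, "e1": 10.0, "z1": 10.0, "a2": 10.0, "b2": 10.0,
    "g2": 10.0, "d2": 15.0, "ch1": 15.0, "ch2": 15.0,
    "nn": 0.5, "cc": 0.5, "mu": 25.0,
}


def _class_mean_vector(linkage: tuple[float, float, float, float, float]) -> StepParameters:
    """Template-consistent 12-parameter mean for one linkage-torsion tuple."""
    e1, z1, a2, b2, g2 = linkage
    torsions = {
        "d1": _DELTA_CANON, "e1": e1, "z1": z1, "a2": a2, "b2": b2,
        "g2": g2, "d2": _DELTA_CANON, "ch1": _CHI_CANON, "ch2": _CHI_CANON,
    }
    _, _, measured = build_step_from_torsions(torsions)
    return measured


def _rows_from_linkages(names, canas, linkages):
    rows = []
    for name, cana, linkage in zip(names, canas, linkages):
        means = _class_mean_vector(linkage)
        row = {"name": name, "cana": cana, "representative": ""}
        for key, value in zip(("d1", "e1", "z1", "a2", "b2", "g2", "d2", "ch1", "ch2", "nn", "cc", "mu"), means.as_vector()):
            row[key] = f"{float(value):.10f}"
            row[f"tol_{key}"] = _DEFAULT_TOL[key]
        rows.append(row)
    return rows


def make_reference_table() -> list[dict]:
    """The packaged 96-class, 14-CANA-code synthetic table (deterministic).

    Classes take their linkage torsions from evenly strided points of the
    lexicographic 6^5 grid, so all 96 mean vectors are pairwise separated
    by at least 6 tolerance units; family membership (and hence the CANA
    code) follows table order. Not an authoritative published class
    table — a converter can import real tables through the same CSV
    schema.
    """
    products = list(itertools.product(_GRID, repeat=5))
    stride = len(products) // 96  # 81
    linkages = [products[i * stride] for i in range(96)]
    names, canas = [], []
    for prefix, cana, size in FAMILY_SIZES:
        for j in range(size):
            names.append(f"{prefix}{j:02d}")
            canas.append(cana)
    return _rows_from_linkages(names, canas, linkages)


def make_test_table(n_classes: int, seed: int = 0) -> list[dict]:
    """Small seeded synthetic table with well-separated class means.

    Intended for unit tests (load with ``allow_small=True``). Class
    names are TC00, TC01, ...; CANA codes cycle through the 14 codes.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    products = list(itertools.product(_GRID, repeat=5))
    idx = rng.choice(len(products), size=n_classes, replace=False)
    linkages = [products[i] for i in sorted(idx)]
    names = [f"TC{i:02d}" for i in range(n_classes)]
    canas = [CANA_CODES[i % len(CANA_CODES)] for i in range(n_classes)]
    return _rows_from_linkages(names, canas, linkages)


def make_distribution_set(
    structure: Structure,
    n: int = 200,
    seed: int = 0,
    bond_sigma: float = 0.012,
    angle_sigma: float = 1.5,
    dictionary=None,
):
    """Synthetic reference distributions for every term measurable on a
    structure, centered on the measured (ideal) values.

    Emulates per-term empirical samples from a curated reference set:
    normal scatter of ``bond_sigma`` angstroms / ``angle_sigma`` degrees
    around the ideal value, with matching CSD-style mean/sigma. Keyed by
    term name; seeded and reproducible.
    """
    from .valgeom import enumerate_terms, load_term_dictionary

    if dictionary is None:
        dictionary = load_term_dictionary()
    centers: dict[str, tuple[str, float]] = {}
    for chain in structure.models[0].chains:
        prev = None
        for res in chain.residues:
            for term, value in enumerate_terms(res, dictionary, prev_residue=prev):
                centers.setdefault(term.term_name, (term.term_type, value))
            prev = res
    dists = {}
    for i, (name, (ttype, value)) in enumerate(sorted(centers.items())):
        sigma = bond_sigma if ttype == "bond" else angle_sigma
        dists[name] = make_reference_distribution(
            name, shape="normal", params={"loc": value, "scale": sigma},
            n=n, seed=seed + i, csd_mean=value, csd_sigma=sigma,
        )
    return dists


_TABLE_COLUMNS = ["name", "cana"] + [
    c for key in ("d1", "e1", "z1", "a2", "b2", "g2", "d2", "ch1", "ch2", "nn", "cc", "mu")
    for c in (key, f"tol_{key}")
] + ["representative"]


def write_table_csv(rows: list[dict], path) -> None:
    """Write a class table in the documented CSV layout."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_TABLE_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
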
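"""NtC class assignment, confal scoring and CANA mapping.

Each dinucleotide step is compared against a reference table of 96 NtC
classes (organized into the 14 codes of the Conformational Alphabet of
Nucleic Acids). The nearest class in tolerance-scaled 12-parameter space
is the candidate assignment; a Cartesian RMSD gate against the class
representative decides between a firm assignment and the NANT
("not assigned") pseudo-class. The confal score expresses the quality of
the 12-parameter match on a 0 (no match) to 100 (perfect match) scale.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .geometry import angular_difference, superpose
from .model import PARAM_COLUMNS, Structure, read_structure
from .steps import DinucleotideStep, StepParameters, compute_step_parameters, find_steps

__all__ = [
    "NtCClassRecord",
    "NtCTable",
    "StepAssignment",
    "ConnectivityReport",
    "TableError",
    "NANT_THRESHOLD",
    "load_ntc_table",
    "load_default_table",
    "class_distance",
    "confal_score",
    "assign_ntc",
    "structure_confal",
    "map_cana",
    "evaluate_connectivity",
    "step_rmsd_atoms",
]

#: default RMSD gate (angstroms) separating firm assignments from NANT;
#: steps beyond ~0.8 A are conformationally remote from every class
NANT_THRESHOLD = 0.5

#: superposition atom set covering the sugar-to-sugar unit:
#: backbone + C1' + glycosidic N of both residues
RMSD_ATOMS_1 = ("C5'", "C4'", "C3'", "O3'", "C1'")
RMSD_ATOMS_2 = ("P", "O5'", "C5'", "C4'", "C3'", "O3'", "C1'")

_LN2 = math.log(2.0)

#: indices of angular components of the 12-vector (all except nn, cc)
_ANGULAR_MASK = np.array([k not in ("nn", "cc") for k in PARAM_COLUMNS])


class TableError(ValueError):
    """Reference table failed validation at load time."""


@dataclass
class NtCClassRecord:
    """One reference NtC class: centroid, tolerances, representative."""

    name: str
    cana: str
    means: StepParameters
    tolerances: np.ndarray  # 12 positive half-widths (deg / angstrom)
    representative: Structure
    rep_step: DinucleotideStep
    rep_params: StepParameters
    rep_coords: np.ndarray  # step_rmsd_atoms order


class NtCTable:
    """Ordered, validated collection of NtC class records."""

    def __init__(self, records: list[NtCClassRecord]):
        self.records = records
        self._by_name = {r.name: r for r in records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, name: str) -> NtCClassRecord:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown NtC class {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def cana_codes(self) -> set[str]:
        return {r.cana for r in self.records}


@dataclass
class StepAssignment:
    """Result of assigning one step to the NtC alphabet.

    When the RMSD gate rejects the nearest class the assignment is
    NANT/NAN, but ``candidate``, ``rmsd``, ``confal`` and the deviation
    vector still describe the nearest class for diagnostics.
    """

    step_id: str
    ntc: str  # class name or "NANT"
    cana: str  # CANA code or "NAN"
    candidate: str  # nearest class regardless of the gate
    confal: float  # [0, 100]
    rmsd: float  # angstroms to the candidate representative
    per_parameter_deviation: np.ndarray  # wrapped differences, 12-vector
    distance_to_class: float


@dataclass
class ConnectivityReport:
    """Continuity of a hypothetical class replacement with its neighbours."""

    rmsd_to_prev: float
    rmsd_to_next: float
    torsion_deviations_prev: dict[str, float]
    torsion_deviations_next: dict[str, float]


def step_rmsd_atoms(step: DinucleotideStep) -> np.ndarray:
    """Coordinates of the superposition atom set, fixed order (14 x 3)."""
    r1, r2 = step.residue_1, step.residue_2
    names1 = RMSD_ATOMS_1 + (r1.glycosidic_nitrogen,)
    names2 = RMSD_ATOMS_2 + (r2.glycosidic_nitrogen,)
    coords = [r1.pos(n) for n in names1] + [r2.pos(n) for n in names2]
    return np.array(coords)


def _deviation_vector(p: StepParameters, means: StepParameters) -> np.ndarray:
    dp = p.as_vector()
    dm = means.as_vector()
    out = np.empty(12)
    for i in range(12):
        if _ANGULAR_MASK[i]:
            out[i] = angular_difference(dp[i], dm[i])
        else:
            out[i] = dp[i] - dm[i]
    return out


def class_distance(p: StepParameters, c: NtCClassRecord) -> float:
    """Tolerance-scaled Euclidean distance in 12-parameter space.

    d = sqrt(sum_j (delta_j / w_j)^2) with wrapped angular differences.
    A step exactly one tolerance away in a single parameter scores 1.
    """
    dev = _deviation_vector(p, c.means)
    return float(np.sqrt(np.sum((dev / c.tolerances) ** 2)))


def confal_score(p: StepParameters, c: NtCClassRecord) -> float:
    """Conformational-match score in [0, 100].

    Per-parameter Gaussian kernel s_j = 100 * exp(-ln2 * (delta_j/w_j)^2)
    (a one-tolerance deviation halves the parameter score), combined as
    the geometric mean over the 12 parameters. 100 at an exact match,
    decaying toward 0 for remote descriptors.
    """
    dev = _deviation_vector(p, c.means)
    z2 = (dev / c.tolerances) ** 2
    return float(100.0 * math.exp(-_LN2 * float(np.mean(z2))))


def assign_ntc(
    step: DinucleotideStep,
    p: StepParameters,
    table: NtCTable,
    nant_threshold: float = NANT_THRESHOLD,
) -> StepAssignment:
    """Assign a step to its nearest NtC class, gated by Cartesian RMSD.

    The candidate is the argmin of :func:`class_distance` over the table
    (ties broken by table order); RMSD superposes the step's defined atom
    set onto the candidate representative. RMSD above ``nant_threshold``
    yields NANT/NAN while retaining all diagnostics.
    """
    distances = np.array([class_distance(p, c) for c in table])
    best = int(np.argmin(distances))
    cand = table.records[best]
    coords = step_rmsd_atoms(step)
    rmsd = superpose(coords, cand.rep_coords).rmsd
    confal = confal_score(p, cand)
    rejected = rmsd > nant_threshold
    return StepAssignment(
        step_id=step.step_id,
        ntc="NANT" if rejected else cand.name,
        cana="NAN" if rejected else cand.cana,
        candidate=cand.name,
        confal=confal,
        rmsd=rmsd,
        per_parameter_deviation=_deviation_vector(p, cand.means),
        distance_to_class=float(distances[best]),
    )


def structure_confal(assignments, calibration=None) -> tuple[float, float | None]:
    """Aggregate confal of a structure: geometric mean over steps.

    NANT steps contribute their diagnostic confal. When ``calibration``
    (an iterable of aggregate-confal values from a calibration
    population) is given, the aggregate's Hazen percentile within it is
    returned as the second element, else None.
    """
    values = np.array([a.confal for a in assignments], dtype=float)
    if values.size == 0:
        raise ValueError("structure_confal needs at least one assignment")
    if np.any(values <= 0.0):
        aggregate = 0.0
    else:
        aggregate = float(np.exp(np.mean(np.log(values))))
    percentile = None
    if calibration is not None:
        from .valgeom import hazen_cdf  # shared empirical-CDF convention

        sample = np.sort(np.asarray(list(calibration), dtype=float))
        percentile = 100.0 * hazen_cdf(sample, aggregate)
    return aggregate, percentile


def map_cana(ntc_name: str, table: NtCTable) -> str:
    """CANA code of an NtC class name; the NANT pseudo-class maps to NAN."""
    if ntc_name == "NANT":
        return "NAN"
    return table[ntc_name].cana


#: step-parameter names measured on the 5'-side / 3'-side residue
_PREV_SHARED = ("d1", "e1", "z1", "ch1")
_NEXT_SHARED = ("a2", "b2", "g2", "d2", "ch2")


def _res_coords(step: DinucleotideStep, which: int) -> np.ndarray:
    coords = step_rmsd_atoms(step)
    return coords[:6] if which == 1 else coords[6:]


def evaluate_connectivity(
    prev_step: DinucleotideStep,
    step: DinucleotideStep,
    next_step: DinucleotideStep,
    target_class: NtCClassRecord | str,
    table: NtCTable,
) -> ConnectivityReport:
    """Continuity check for replacing ``step`` by a target class geometry.

    ``prev_step`` must share the step's 5' residue (as its residue_2) and
    ``next_step`` its 3' residue (as its residue_1). For each neighbour
    the target representative is superposed on the step's non-shared
    residue and the RMSD taken over the shared-residue atoms; the torsion
    deviations are the wrapped differences between the target class means
    and the observed step values on that neighbour's side of the step
    (5': delta1 epsilon1 zeta1 chi1; 3': alpha2 beta2 gamma2 delta2 chi2).
    """
    if isinstance(target_class, str):
        target_class = table[target_class]
    if prev_step.residue_2.label != step.residue_1.label:
        raise ValueError(
            f"steps not adjacent: {prev_step.step_id} does not share the 5' residue of {step.step_id}"
        )
    if next_step.residue_1.label != step.residue_2.label:
        raise ValueError(
            f"steps not adjacent: {next_step.step_id} does not share the 3' residue of {step.step_id}"
        )
    p = compute_step_parameters(step)
    mean = {k: getattr(target_class.means, k) for k in PARAM_COLUMNS}
    dev_prev = {k: angular_difference(mean[k], getattr(p, k)) for k in _PREV_SHARED}
    dev_next = {k: angular_difference(mean[k], getattr(p, k)) for k in _NEXT_SHARED}

    rep1 = _res_coords(target_class.rep_step, 1)
    rep2 = _res_coords(target_class.rep_step, 2)
    obs1 = _res_coords(step, 1)
    obs2 = _res_coords(step, 2)
    # anchor on residue 2 (not shared with prev), evaluate over residue 1
    fit = superpose(rep2, obs2)
    moved1 = fit.transform(rep1)
    rmsd_prev = float(np.sqrt(np.mean(np.sum((moved1 - obs1) ** 2, axis=1))))
    # anchor on residue 1 (not shared with next), evaluate over residue 2
    fit = superpose(rep1, obs1)
    moved2 = fit.transform(rep2)
    rmsd_next = float(np.sqrt(np.mean(np.sum((moved2 - obs2) ** 2, axis=1))))
    return ConnectivityReport(
        rmsd_to_prev=rmsd_prev,
        rmsd_to_next=rmsd_next,
        torsion_deviations_prev=dev_prev,
        torsion_deviations_next=dev_next,
    )


# ---------------------------------------------------------------------------
# table loading
# ---------------------------------------------------------------------------

_ANGLE_KEYS = tuple(k for k in PARAM_COLUMNS if k not in ("nn", "cc"))
_SELF_CONSISTENCY_ANGLE = 0.5  # degrees
_SELF_CONSISTENCY_DIST = 0.05  # angstroms


def _build_record(row: dict, base_dir: Path) -> NtCClassRecord:
    from .fixtures import build_step_from_torsions

    means = StepParameters(**{k: float(row[k]) for k in PARAM_COLUMNS})
    tol = np.array([float(row[f"tol_{k}"]) for k in PARAM_COLUMNS])
    if np.any(tol <= 0):
        raise TableError(f"class {row['name']}: non-positive tolerance")
    rep_path = (row.get("representative") or "").strip()
    if rep_path:
        structure = read_structure(base_dir / rep_path)
        chain = structure.models[0].chains[0]
        steps = find_steps(chain)
        if len(steps) != 1:
            raise TableError(f"class {row['name']}: representative must contain exactly one step")
        rep_step = steps[0]
        rep_params = compute_step_parameters(rep_step)
    else:
        torsions = {k: float(row[k]) for k in StepParameters.TORSION_NAMES}
        structure, rep_step, rep_params = build_step_from_torsions(torsions)
    for i, key in enumerate(PARAM_COLUMNS):
        got = getattr(rep_params, key)
        want = getattr(means, key)
        if key in _ANGLE_KEYS:
            err = abs(angular_difference(got, want))
            lim = _SELF_CONSISTENCY_ANGLE
        else:
            err = abs(got - want)
            lim = _SELF_CONSISTENCY_DIST
        if err > lim:
            raise TableError(
                f"class {row['name']}: representative inconsistent with means "
                f"({key}: {got:.3f} vs {want:.3f})"
            )
    return NtCClassRecord(
        name=row["name"],
        cana=row["cana"],
        means=means,
        tolerances=tol,
        representative=structure,
        rep_step=rep_step,
        rep_params=rep_params,
        rep_coords=step_rmsd_atoms(rep_step),
    )


def load_ntc_table(path, allow_small: bool = False) -> NtCTable:
    """Load and validate an NtC reference table from CSV.

    A full table must contain exactly 96 uniquely named classes mapped
    onto exactly 14 distinct CANA codes; ``allow_small`` relaxes the
    cardinality checks for unit-test tables. Representative coordinates
    (loaded from the referenced mmCIF fragment, or rebuilt from the class
    torsions when the column is empty) must re-measure to the stored
    means within 0.5 degrees / 0.05 angstroms, else the load fails naming
    the offending record.
    """
    path = Path(path)
    with path.open() as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise TableError(f"{path}: empty table")
    names = [r["name"] for r in rows]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise TableError(f"{path}: duplicated class name(s): {sorted(dupes)}")
    records = sorted(rows, key=lambda r: r["name"])  # alphabetical = deterministic ties
    table = NtCTable([_build_record(r, path.parent) for r in records])
    if not allow_small:
        if len(table) != 96:
            raise TableError(f"{path}: expected 96 classes, found {len(table)}")
        if len(table.cana_codes) != 14:
            raise TableError(f"{path}: expected 14 CANA codes, found {len(table.cana_codes)}")
    return table


@lru_cache(maxsize=1)
def load_default_table() -> NtCTable:
    """The packaged (synthetic, self-consistent) 96-class table."""
    with resources.as_file(resources.files("ntckit.data").joinpath("ntc_classes.csv")) as p:
        return load_ntc_table(p)
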
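"""Dinucleotide step detection and the 12-parameter NtC descriptor.

A *step* is the sugar-to-sugar dinucleotide unit joined by the central
phosphodiester linkage. Each step is described by 12 parameters:

* seven backbone torsions delta(1), epsilon(1), zeta(1), alpha(2),
  beta(2), gamma(2), delta(2),
* the two glycosidic torsions chi(1), chi(2),
* the distance NN between the glycosidic nitrogens (N9 for purines,
  N1 for pyrimidines) of the two bases,
* the distance CC between the two C1' atoms,
* the pseudo-torsion mu = N-C1'(1)-C1'(2)-N.

The module also computes the eta/theta pseudo-torsion pair assigned to
each interior nucleotide (the Ramachandran-like reduced representation)
and the trinucleotide overlap table pairing eta/theta with the NtC
classes of the two overlapping steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import GeometryError, dihedral, distance
from .model import PARAM_COLUMNS, Chain, Residue

logger = logging.getLogger("ntckit")

__all__ = [
    "StepParameters",
    "DinucleotideStep",
    "PseudoTorsions",
    "CONNECTIVITY_CUTOFF",
    "find_steps",
    "compute_step_parameters",
    "compute_eta_theta",
    "step_overlap_table",
    "steps_to_dataframe",
]

#: default O3'(i)-P(i+1) covalent-connectivity cutoff, angstroms
CONNECTIVITY_CUTOFF = 2.0

#: heavy atoms required in residue 1 / residue 2 of a step
#: (glycosidic nitrogen handled separately, it is base-type dependent)
_REQUIRED_RES1 = ("C5'", "C4'", "C3'", "O3'", "C1'", "O4'")
_REQUIRED_RES2 = ("P", "O5'", "C5'", "C4'", "C3'", "O3'", "C1'", "O4'")

#: second base atom of the chi quadruple, per base family
_CHI_BASE_ATOM = {"purine": "C4", "pyrimidine": "C2"}


@dataclass(frozen=True)
class StepParameters:
    """The 12-component NtC descriptor of one dinucleotide step."""

    d1: float
    e1: float
    z1: float
    a2: float
    b2: float
    g2: float
    d2: float
    ch1: float
    ch2: float
    nn: float
    cc: float
    mu: float

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_COLUMNS], dtype=float)

    @classmethod
    def from_vector(cls, vec) -> "StepParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (12,):
            raise ValueError("StepParameters vector must have exactly 12 components")
        return cls(**dict(zip(PARAM_COLUMNS, map(float, vec))))

    #: indices of angular components within the 12-vector (all but nn, cc)
    ANGULAR = tuple(i for i, k in enumerate(PARAM_COLUMNS) if k not in ("nn", "cc"))

    #: indices of the 9 true torsions, in restraint order
    TORSION_NAMES = ("d1", "e1", "z1", "a2", "b2", "g2", "d2", "ch1", "ch2")


@dataclass
class DinucleotideStep:
    """One sugar-to-sugar dinucleotide unit (5'->3' residue order)."""

    residue_1: Residue
    residue_2: Residue

    @property
    def step_id(self) -> str:
        return f"{self.residue_1.chain_id}.{self.residue_1.seq_id}-{self.residue_2.seq_id}"


@dataclass(frozen=True)
class PseudoTorsions:
    """eta/theta pseudo-torsion pair of one interior nucleotide."""

    residue: Residue
    eta: float
    theta: float


def _chi_atoms(res: Residue) -> tuple[str, str, str, str]:
    n = res.glycosidic_nitrogen
    base2 = _CHI_BASE_ATOM["purine" if res.is_purine else "pyrimidine"]
    return ("O4'", "C1'", n, base2)


def _step_atoms_present(res1: Residue, res2: Residue) -> bool:
    need1 = _REQUIRED_RES1 + (res1.glycosidic_nitrogen, _CHI_BASE_ATOM["purine" if res1.is_purine else "pyrimidine"])
    need2 = _REQUIRED_RES2 + (res2.glycosidic_nitrogen, _CHI_BASE_ATOM["purine" if res2.is_purine else "pyrimidine"])
    return res1.has_atoms(need1) and res2.has_atoms(need2)


def find_steps(
    chain: Chain,
    cutoff: float = CONNECTIVITY_CUTOFF,
    skipped: list | None = None,
) -> list[DinucleotideStep]:
    """Detect dinucleotide steps along a nucleotide chain.

    A consecutive residue pair forms a step when the O3'(i)-P(i+1)
    distance is at most ``cutoff`` (covalent continuity) and both
    residues carry all atoms required by the 12-parameter descriptor.
    Failing pairs are skipped with a logged reason code
    (``chain_break`` or ``missing_atoms``); pass a list as ``skipped``
    to also collect (pair label, reason) tuples.
    """
    steps = []
    for res1, res2 in zip(chain.residues, chain.residues[1:]):
        pair = f"{res1.label}-{res2.seq_id}"
        o3 = res1.atom("O3'")
        p = res2.atom("P")
        if o3 is None or p is None or distance(o3.position, p.position) > cutoff:
            logger.info("skip %s: chain_break", pair)
            if skipped is not None:
                skipped.append((pair, "chain_break"))
            continue
        if not _step_atoms_present(res1, res2):
            logger.info("skip %s: missing_atoms", pair)
            if skipped is not None:
                skipped.append((pair, "missing_atoms"))
            continue
        steps.append(DinucleotideStep(residue_1=res1, residue_2=res2))
    return steps


def compute_step_parameters(step: DinucleotideStep) -> StepParameters:
    """Measure the 12-parameter descriptor of a step.

    Torsion quadruples follow the standard backbone definitions
    (alpha: O3'(i)-P-O5'-C5'; beta: P-O5'-C5'-C4'; gamma: O5'-C5'-C4'-C3';
    delta: C5'-C4'-C3'-O3'; epsilon: C4'-C3'-O3'-P(+1);
    zeta: C3'-O3'-P(+1)-O5'(+1); chi: O4'-C1'-N9-C4 for purines,
    O4'-C1'-N1-C2 for pyrimidines). Degenerate geometry raises
    :class:`~ntckit.geometry.GeometryError` naming the torsion.
    """
    r1, r2 = step.residue_1, step.residue_2

    def tors(label, *specs):
        pts = [(r1 if which == 1 else r2).pos(name) for which, name in specs]
        try:
            return dihedral(*pts)
        except GeometryError as exc:
            raise GeometryError(f"step {step.step_id}: torsion {label} undefined: {exc}") from exc

    chi1 = _chi_atoms(r1)
    chi2 = _chi_atoms(r2)
    n1 = r1.pos(r1.glycosidic_nitrogen)
    n2 = r2.pos(r2.glycosidic_nitrogen)
    c1a = r1.pos("C1'")
    c1b = r2.pos("C1'")
    return StepParameters(
        d1=tors("delta_1", (1, "C5'"), (1, "C4'"), (1, "C3'"), (1, "O3'")),
        e1=tors("epsilon_1", (1, "C4'"), (1, "C3'"), (1, "O3'"), (2, "P")),
        z1=tors("zeta_1", (1, "C3'"), (1, "O3'"), (2, "P"), (2, "O5'")),
        a2=tors("alpha_2", (1, "O3'"), (2, "P"), (2, "O5'"), (2, "C5'")),
        b2=tors("beta_2", (2, "P"), (2, "O5'"), (2, "C5'"), (2, "C4'")),
        g2=tors("gamma_2", (2, "O5'"), (2, "C5'"), (2, "C4'"), (2, "C3'")),
        d2=tors("delta_2", (2, "C5'"), (2, "C4'"), (2, "C3'"), (2, "O3'")),
        ch1=tors("chi_1", *((1, a) for a in chi1)),
        ch2=tors("chi_2", *((2, a) for a in chi2)),
        nn=distance(n1, n2),
        cc=distance(c1a, c1b),
        mu=dihedral(n1, c1a, c1b, n2),
    )


def compute_eta_theta(chain: Chain, cutoff: float = CONNECTIVITY_CUTOFF) -> list[PseudoTorsions]:
    """eta/theta pseudo-torsions for every interior residue of a chain.

    eta(i) = C4'(i-1)-P(i)-C4'(i)-P(i+1);
    theta(i) = P(i)-C4'(i)-P(i+1)-C4'(i+1).
    Terminal residues are omitted; interior residues lacking the needed
    P/C4' atoms, or not covalently continuous with their neighbours
    (O3'-P distance check, applied when O3' atoms are present), are
    omitted with a log message.
    """
    out = []
    res = chain.residues
    for i in range(1, len(res) - 1):
        prev_r, r, next_r = res[i - 1], res[i], res[i + 1]
        needed = [
            prev_r.atom("C4'"), r.atom("P"), r.atom("C4'"),
            next_r.atom("P"), next_r.atom("C4'"),
        ]
        if any(a is None for a in needed):
            logger.info("eta/theta: skip %s (missing atoms)", r.label)
            continue
        connected = True
        for a, b in ((prev_r, r), (r, next_r)):
            o3 = a.atom("O3'")
            p = b.atom("P")
            if o3 is not None and p is not None and distance(o3.position, p.position) > cutoff:
                connected = False
        if not connected:
            logger.info("eta/theta: skip %s (chain break)", r.label)
            continue
        c4p, pp, c4, pn, c4n = (a.position for a in needed)
        try:
            eta = dihedral(c4p, pp, c4, pn)
            theta = dihedral(pp, c4, pn, c4n)
        except GeometryError:
            logger.info("eta/theta: skip %s (degenerate geometry)", r.label)
            continue
        out.append(PseudoTorsions(residue=r, eta=eta, theta=theta))
    return out


def step_overlap_table(
    chain: Chain,
    assignments: dict[str, "object"],
    rmsd_filter: float | None = None,
    assigned_only: bool = True,
    cutoff: float = CONNECTIVITY_CUTOFF,
) -> pd.DataFrame:
    """Trinucleotide table pairing each central residue's eta/theta with
    the NtC classes of its two overlapping steps.

    ``assignments`` maps step_id to a StepAssignment. A record is emitted
    for each interior residue whose both flanking steps have assignments;
    with ``assigned_only`` (default) NANT flanks are excluded, and with
    ``rmsd_filter`` set, both steps must have rmsd at or below the filter
    (the quality convention used for reference-grade steps).
    """
    pseudo = {pt.residue.label: pt for pt in compute_eta_theta(chain, cutoff=cutoff)}
    rows = []
    res = chain.residues
    for i in range(1, len(res) - 1):
        central = res[i]
        pt = pseudo.get(central.label)
        if pt is None:
            continue
        id5 = f"{chain.chain_id}.{res[i-1].seq_id}-{central.seq_id}"
        id3 = f"{chain.chain_id}.{central.seq_id}-{res[i+1].seq_id}"
        a5 = assignments.get(id5)
        a3 = assignments.get(id3)
        if a5 is None or a3 is None:
            continue
        if assigned_only and ("NANT" in (a5.ntc, a3.ntc)):
            continue
        if rmsd_filter is not None and (a5.rmsd > rmsd_filter or a3.rmsd > rmsd_filter):
            continue
        rows.append({
            "chain": chain.chain_id,
            "seq_id": central.seq_id,
            "comp_id": central.comp_id,
            "eta": pt.eta,
            "theta": pt.theta,
            "ntc_5p": a5.ntc,
            "ntc_3p": a3.ntc,
            "cana_5p": a5.cana,
            "cana_3p": a3.cana,
        })
    return pd.DataFrame(rows, columns=[
        "chain", "seq_id", "comp_id", "eta", "theta",
        "ntc_5p", "ntc_3p", "cana_5p", "cana_3p",
    ])


def steps_to_dataframe(records) -> pd.DataFrame:
    """Tabulate (step, assignment, parameters) triples, columns matching
    the ``_ntc_step`` mmCIF category."""
    rows = []
    for step, asg, params in records:
        row = {
            "step_id": step.step_id,
            "chain": step.residue_1.chain_id,
            "seq_id_1": step.residue_1.seq_id,
            "comp_id_1": step.residue_1.comp_id,
            "seq_id_2": step.residue_2.seq_id,
            "comp_id_2": step.residue_2.comp_id,
            "ntc": asg.ntc,
            "cana": asg.cana,
            "confal": round(asg.confal, 1),
            "rmsd": round(asg.rmsd, 4),
        }
        row.update({k: round(v, 4) for k, v in zip(PARAM_COLUMNS, params.as_vector())})
        rows.append(row)
    return pd.DataFrame(rows, columns=[
        "step_id", "chain", "seq_id_1", "comp_id_1", "seq_id_2", "comp_id_2",
        "ntc", "cana", "confal", "rmsd", *PARAM_COLUMNS,
    ])
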
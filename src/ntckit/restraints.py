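"""Torsion-restraint file generation for refinement programs.

Given a dinucleotide step and a target NtC class, emits the nine
backbone/glycosidic torsion restraints (delta1 epsilon1 zeta1 alpha2
beta2 gamma2 delta2 chi1 chi2) with targets at the class means, in one
of four dialects:

* ``refmac``  — external torsion restraint records,
* ``phenix``  — geometry-edits dihedral blocks,
* ``buster``  — best-effort NOTE-style dihedral records,
* ``generic`` — the toolkit's own CSV, the only dialect with a
  guaranteed round-trip parser (used by the test suite).

Vendor keyword syntax varies between program versions; the refmac,
phenix and buster templates are documented approximations meant to be
post-edited if a specific version requires it.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

from .geometry import wrap_angle
from .steps import DinucleotideStep

__all__ = [
    "TorsionRestraint",
    "DIALECTS",
    "make_restraints",
    "batch_restraints",
    "parse_generic",
    "restraints_for_step",
]

DIALECTS = ("refmac", "phenix", "buster", "generic")

#: minimum restraint sigma, degrees
SIGMA_FLOOR = 2.0

#: torsion label -> (residue index, atom name) x 4 quadruples
_TORSION_ATOMS = {
    "d1": ((1, "C5'"), (1, "C4'"), (1, "C3'"), (1, "O3'")),
    "e1": ((1, "C4'"), (1, "C3'"), (1, "O3'"), (2, "P")),
    "z1": ((1, "C3'"), (1, "O3'"), (2, "P"), (2, "O5'")),
    "a2": ((1, "O3'"), (2, "P"), (2, "O5'"), (2, "C5'")),
    "b2": ((2, "P"), (2, "O5'"), (2, "C5'"), (2, "C4'")),
    "g2": ((2, "O5'"), (2, "C5'"), (2, "C4'"), (2, "C3'")),
    "d2": ((2, "C5'"), (2, "C4'"), (2, "C3'"), (2, "O3'")),
}


@dataclass(frozen=True)
class TorsionRestraint:
    """One dihedral restraint: four atom selectors, target and sigma."""

    label: str
    atoms: tuple[tuple[str, str, str], ...]  # 4 x (chain, seq_id, atom name)
    target: float  # degrees, (-180, 180]
    sigma: float  # degrees, > 0

    def __post_init__(self) -> None:
        if len(self.atoms) != 4:
            raise ValueError("a torsion restraint needs exactly 4 atoms")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _chi_quadruple(res) -> tuple[tuple[str, str], ...]:
    n = res.glycosidic_nitrogen
    base2 = "C4" if res.is_purine else "C2"
    return (("O4'",), ("C1'",), (n,), (base2,))


def restraints_for_step(step: DinucleotideStep, target_class, sigma_policy="half_tolerance") -> list[TorsionRestraint]:
    """The nine torsion restraints steering a step toward a class.

    ``sigma_policy`` is either the string ``"half_tolerance"`` (sigma =
    class tolerance / 2, floored at 2 degrees) or a fixed positive number
    of degrees.
    """
    from .model import PARAM_COLUMNS  # tolerance vector ordering

    residues = {1: step.residue_1, 2: step.residue_2}
    tol = {k: float(t) for k, t in zip(PARAM_COLUMNS, target_class.tolerances)}
    out = []
    for label in ("d1", "e1", "z1", "a2", "b2", "g2", "d2", "ch1", "ch2"):
        if label in _TORSION_ATOMS:
            quad = _TORSION_ATOMS[label]
        else:
            ridx = 1 if label == "ch1" else 2
            quad = tuple((ridx, names[0]) for names in _chi_quadruple(residues[ridx]))
        atoms = tuple(
            (residues[r].chain_id, residues[r].seq_id, name) for r, name in quad
        )
        if isinstance(sigma_policy, str):
            if sigma_policy != "half_tolerance":
                raise ValueError(f"unknown sigma policy {sigma_policy!r}")
            sigma = max(tol[label] / 2.0, SIGMA_FLOOR)
        else:
            sigma = float(sigma_policy)
            if sigma <= 0:
                raise ValueError("fixed sigma must be positive")
        out.append(TorsionRestraint(
            label=label,
            atoms=atoms,
            target=wrap_angle(getattr(target_class.means, label)),
            sigma=sigma,
        ))
    return out


def _emit_refmac(restraints) -> str:
    lines = []
    for r in restraints:
        sel = " ".join(
            f"{kw} chain {c} resi {s} atom {a}"
            for kw, (c, s, a) in zip(("first", "next", "next", "next"), r.atoms)
        )
        lines.append(
            f"external torsion {sel} value {r.target:.1f} sigma {r.sigma:.1f} period 1"
        )
    return "\n".join(lines) + "\n"


def _emit_phenix(restraints) -> str:
    parts = []
    for r in restraints:
        atom_lines = "\n".join(
            f"    atom_selection_{i+1} = chain {c} and resseq {s} and name {a}"
            for i, (c, s, a) in enumerate(r.atoms)
        )
        parts.append(
            "  dihedral {\n"
            f"{atom_lines}\n"
            f"    angle_ideal = {r.target:.1f}\n"
            f"    sigma = {r.sigma:.1f}\n"
            "    periodicity = 1\n"
            "  }"
        )
    return "refinement.geometry_restraints.edits {\n" + "\n".join(parts) + "\n}\n"


def _emit_buster(restraints) -> str:
    lines = []
    for r in restraints:
        sel = " ".join(f"{c}|{s}|{a}" for c, s, a in r.atoms)
        lines.append(f"NOTE BUSTER_UTIL_DIHE {sel} {r.target:.1f} {r.sigma:.1f}")
    return "\n".join(lines) + "\n"


_GENERIC_HEADER = [
    "label",
    "chain1", "seq1", "atom1", "chain2", "seq2", "atom2",
    "chain3", "seq3", "atom3", "chain4", "seq4", "atom4",
    "target_deg", "sigma_deg",
]


def _emit_generic(restraints) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(_GENERIC_HEADER)
    for r in restraints:
        row = [r.label]
        for c, s, a in r.atoms:
            row.extend([c, s, a])
        row.extend([f"{r.target:.4f}", f"{r.sigma:.4f}"])
        w.writerow(row)
    return buf.getvalue()


_EMITTERS = {
    "refmac": _emit_refmac,
    "phenix": _emit_phenix,
    "buster": _emit_buster,
    "generic": _emit_generic,
}


def make_restraints(step: DinucleotideStep, target_class, dialect: str = "generic",
                    sigma_policy="half_tolerance") -> str:
    """Restraint text for one step in the requested dialect."""
    if dialect not in _EMITTERS:
        raise ValueError(f"unknown dialect {dialect!r}; supported: {', '.join(DIALECTS)}")
    return _EMITTERS[dialect](restraints_for_step(step, target_class, sigma_policy))


def batch_restraints(steps_by_id: dict[str, DinucleotideStep], edits, table,
                     dialect: str = "generic", sigma_policy="half_tolerance") -> str:
    """Concatenated restraint blocks for a list of (step_id, class) edits.

    All step ids and class names are checked before any output is
    produced; a step id listed twice with different target classes is a
    conflict and raises.
    """
    edits = list(edits)
    targets: dict[str, str] = {}
    for step_id, class_name in edits:
        if step_id not in steps_by_id:
            raise KeyError(f"unknown step id {step_id!r}")
        if class_name not in table:
            raise KeyError(f"unknown NtC class {class_name!r}")
        if targets.get(step_id, class_name) != class_name:
            raise ValueError(f"conflicting target classes for step {step_id}")
        targets[step_id] = class_name
    comment = "#" if dialect in ("generic", "refmac", "buster") else "#"
    parts = [f"{comment} torsion restraints ({dialect}), {len(edits)} step edit(s)\n"]
    for step_id, class_name in edits:
        parts.append(f"{comment} step {step_id} -> {class_name}\n")
        parts.append(make_restraints(steps_by_id[step_id], table[class_name], dialect, sigma_policy))
    return "".join(parts)


def parse_generic(text: str) -> list[TorsionRestraint]:
    """Parse the generic CSV dialect back into restraint objects."""
    header = ",".join(_GENERIC_HEADER)
    rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#") and ln != header]
    out = []
    for rec in csv.DictReader(io.StringIO("\n".join([header] + rows))):
        atoms = tuple(
            (rec[f"chain{i}"], rec[f"seq{i}"], rec[f"atom{i}"]) for i in (1, 2, 3, 4)
        )
        out.append(TorsionRestraint(
            label=rec["label"],
            atoms=atoms,
            target=float(rec["target_deg"]),
            sigma=float(rec["sigma_deg"]),
        ))
    return out
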
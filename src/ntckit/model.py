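"""Uniform structural data model over mmCIF/PDB files.

A thin, explicit hierarchy (Structure > Model > Chain > Residue > Atom)
built on top of gemmi's readers and writers. Author chain IDs, residue
numbers and insertion codes are preserved; hetero and water residues are
retained but carry ``moiety_class == "other"`` so downstream nucleic-acid
analysis can skip them.

Annotated output is written as mmCIF extended with two custom categories,
``_ntc_step`` (per-dinucleotide NtC/CANA assignment plus the 12-parameter
descriptor) and ``_ntc_valgeom`` (per bond/angle valence-geometry verdicts).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger("ntckit")

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Model",
    "Structure",
    "ParseError",
    "EmptyStructureError",
    "AltlocError",
    "ConsistencyError",
    "read_structure",
    "write_structure",
    "resolve_altlocs",
    "extract_na_chains",
    "write_annotated_cif",
    "read_step_table",
    "read_valgeom_table",
    "component_info",
]

RIBO = "ribonucleotide"
DEOXY = "deoxyribonucleotide"
OTHER = "other"

PURINE_PARENTS = {"A", "G", "DA", "DG"}
PYRIMIDINE_PARENTS = {"C", "U", "DC", "DT", "DU"}

STEP_CATEGORY = "_ntc_step"
VALGEOM_CATEGORY = "_ntc_valgeom"

#: column order of the 12-parameter descriptor in tabular outputs
PARAM_COLUMNS = ("d1", "e1", "z1", "a2", "b2", "g2", "d2", "ch1", "ch2", "nn", "cc", "mu")


class ParseError(ValueError):
    """Input file could not be parsed."""


class EmptyStructureError(ValueError):
    """Parsed file contains no models/chains."""


class AltlocError(ValueError):
    """Requested alternate-location label is unavailable."""


class ConsistencyError(ValueError):
    """Annotations refer to residues absent from the structure."""


def _load_component_table() -> dict[str, tuple[str, str]]:
    table: dict[str, tuple[str, str]] = {}
    with resources.files("ntckit.data").joinpath("components.csv").open() as fh:
        for row in csv.DictReader(fh):
            table[row["comp_id"]] = (row["parent"], row["moiety"])
    return table


_COMPONENTS = _load_component_table()


def component_info(comp_id: str) -> tuple[str, str]:
    """Return (parent component, moiety class) for a residue name.

    Unknown components map to parent "" and moiety "other".
    """
    return _COMPONENTS.get(comp_id.upper(), ("", OTHER))


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    seq_id: str  # author residue number + insertion code, e.g. "10" or "10A"
    comp_id: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def parent_comp(self) -> str:
        return component_info(self.comp_id)[0]

    @property
    def moiety_class(self) -> str:
        return component_info(self.comp_id)[1]

    @property
    def is_nucleotide(self) -> bool:
        return self.moiety_class in (RIBO, DEOXY)

    @property
    def is_purine(self) -> bool:
        return self.parent_comp in PURINE_PARENTS

    @property
    def glycosidic_nitrogen(self) -> str:
        return "N9" if self.is_purine else "N1"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atoms(self, names) -> bool:
        return all(self.atom(n) is not None for n in names)

    def pos(self, name: str) -> np.ndarray:
        a = self.atom(name)
        if a is None:
            raise KeyError(f"{self.chain_id}.{self.seq_id} {self.comp_id}: missing atom {name}")
        return a.position

    @property
    def label(self) -> str:
        return f"{self.chain_id}.{self.seq_id}"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Model:
    num: int
    chains: list[Chain] = field(default_factory=list)


@dataclass
class Structure:
    entry_id: str
    models: list[Model] = field(default_factory=list)
    source_format: str = "mmcif"

    def model(self, index: int = 0) -> Model:
        return self.models[index]

    def find_residue(self, chain_id: str, seq_id: str, model_index: int = 0) -> Residue | None:
        for chain in self.models[model_index].chains:
            if chain.chain_id != chain_id:
                continue
            for res in chain.residues:
                if res.seq_id == str(seq_id):
                    return res
        return None


def _seq_id(seqid: gemmi.SeqId) -> str:
    icode = seqid.icode.strip()
    return f"{seqid.num}{icode}"


def _from_gemmi(st: gemmi.Structure, source_format: str) -> Structure:
    models = []
    for gm in st:
        chains = []
        for gc in gm:
            residues = []
            for gr in gc:
                atoms = [
                    Atom(
                        name=ga.name,
                        element=ga.element.name,
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(max(float(ga.occ), 0.0), 1.0),
                        altloc=ga.altloc if ga.altloc != "\x00" else "",
                        b_factor=float(ga.b_iso),
                    )
                    for ga in gr
                    if ga.element.name != "H"  # all descriptors are heavy-atom based
                ]
                residues.append(
                    Residue(
                        chain_id=gc.name,
                        seq_id=_seq_id(gr.seqid),
                        comp_id=gr.name,
                        atoms=atoms,
                    )
                )
            if residues:
                chains.append(Chain(chain_id=gc.name, residues=residues))
        models.append(Model(num=int(gm.num) if str(gm.num).isdigit() else len(models) + 1, chains=chains))
    return Structure(entry_id=st.name or "XXXX", models=models, source_format=source_format)


def read_structure(path, format: str = "auto") -> Structure:
    """Read an mmCIF or PDB file into the uniform data model.

    ``format`` is one of ``auto``, ``mmcif``, ``pdb``. Author chain IDs,
    residue numbering and insertion codes are preserved. Hydrogens are
    dropped; hetero/water residues are kept with moiety class "other".
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt_map = {
        "auto": gemmi.CoorFormat.Detect,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "pdb": gemmi.CoorFormat.Pdb,
    }
    if format not in fmt_map:
        raise ValueError(f"unknown format {format!r}; expected auto, mmcif or pdb")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path.name}: {exc}") from exc
    if format == "auto":
        source = "pdb" if st.input_format == gemmi.CoorFormat.Pdb else "mmcif"
    else:
        source = format
    structure = _from_gemmi(st, source)
    if not structure.models or not any(m.chains for m in structure.models):
        raise EmptyStructureError(f"{path.name}: no models or chains found")
    return structure


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.entry_id
    for model in structure.models:
        gm = gemmi.Model(model.num)
        for chain in model.chains:
            gc = gemmi.Chain(chain.chain_id)
            for res in chain.residues:
                gr = gemmi.Residue()
                gr.name = res.comp_id
                num = res.seq_id
                icode = ""
                while num and num[-1].isalpha():
                    icode = num[-1] + icode
                    num = num[:-1]
                gr.seqid = gemmi.SeqId(int(num), icode if icode else " ")
                gr.het_flag = "A" if res.is_nucleotide else "H"
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element or atom.name[0])
                    ga.pos = gemmi.Position(*atom.position)
                    ga.occ = atom.occupancy
                    ga.b_iso = atom.b_factor
                    if atom.altloc:
                        ga.altloc = atom.altloc
                    gr.add_atom(ga)
                gc.add_residue(gr)
            gm.add_chain(gc)
        st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path, format: str = "mmcif") -> None:
    """Serialize the data model to mmCIF or PDB."""
    st = _to_gemmi(structure)
    path = Path(path)
    if format == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    elif format == "pdb":
        st.write_pdb(str(path))
    else:
        raise ValueError(f"unknown output format {format!r}")


def resolve_altlocs(structure: Structure, policy: str = "highest_occupancy", label: str | None = None) -> Structure:
    """Collapse alternate locations so each atom name occurs once per residue.

    ``policy="highest_occupancy"`` keeps the highest-occupancy location,
    ties broken by the alphabetically first altloc label. ``policy="label"``
    keeps blank-altloc atoms plus those matching ``label`` and raises
    :class:`AltlocError` when a disordered atom lacks that label.
    """
    if policy not in ("highest_occupancy", "label"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    if policy == "label" and not label:
        raise ValueError("policy 'label' requires a label")
    for model in structure.models:
        for chain in model.chains:
            for res in chain.residues:
                groups: dict[str, list[Atom]] = {}
                order: list[str] = []
                for atom in res.atoms:
                    if atom.name not in groups:
                        groups[atom.name] = []
                        order.append(atom.name)
                    groups[atom.name].append(atom)
                resolved = []
                for name in order:
                    group = groups[name]
                    if len(group) == 1:
                        chosen = group[0]
                    elif policy == "highest_occupancy":
                        chosen = sorted(group, key=lambda a: (-a.occupancy, a.altloc))[0]
                    else:
                        match = [a for a in group if a.altloc in ("", label)]
                        if not match:
                            available = sorted({a.altloc for a in group})
                            raise AltlocError(
                                f"{res.label} {name}: altloc {label!r} absent; available: {available}"
                            )
                        chosen = match[0]
                    chosen.altloc = ""
                    resolved.append(chosen)
                res.atoms = resolved
    return structure


def extract_na_chains(structure: Structure, model_index: int = 0) -> list[Chain]:
    """Return chains filtered to ribo-/deoxyribonucleotide residues.

    Residue order within each chain is preserved; non-nucleotide residues
    (protein, ligands, waters, unknown modified components) are skipped
    with a logged reason. Chains left empty are omitted.
    """
    out = []
    for chain in structure.models[model_index].chains:
        kept = []
        for res in chain.residues:
            if res.is_nucleotide:
                kept.append(res)
            else:
                reason = "unknown_component" if res.comp_id.upper() not in _COMPONENTS else "non_nucleotide"
                logger.warning("skipping %s %s: %s", res.label, res.comp_id, reason)
        if kept:
            out.append(Chain(chain_id=chain.chain_id, residues=kept))
    return out


def _fmt(x: float, nd: int = 3) -> str:
    return f"{x:.{nd}f}"


def write_annotated_cif(structure: Structure, assignments, verdicts, path) -> None:
    """Write coordinates plus NtC-step and valence-geometry annotation categories.

    ``assignments`` is an iterable of (step, StepAssignment, StepParameters)
    triples as produced by the annotation pipeline; ``verdicts`` an iterable
    of ValidationVerdict records. Both may be empty, in which case the
    custom categories are written with zero rows. Every referenced residue
    must exist in ``structure``.
    """
    assignments = list(assignments)
    verdicts = list(verdicts)
    for step, _, _ in assignments:
        for res in (step.residue_1, step.residue_2):
            if structure.find_residue(res.chain_id, res.seq_id) is None:
                raise ConsistencyError(f"step {step.step_id}: residue {res.label} not in structure")
    for v in verdicts:
        if structure.find_residue(v.chain_id, v.seq_id) is None:
            raise ConsistencyError(f"valgeom term {v.term_name}: residue {v.chain_id}.{v.seq_id} not in structure")

    doc = _to_gemmi(structure).make_mmcif_document()
    block = doc.sole_block()

    step_tags = [
        "id", "model", "chain", "seq_id_1", "comp_id_1", "seq_id_2", "comp_id_2",
        "ntc", "cana", "confal", "rmsd", *PARAM_COLUMNS,
    ]
    loop = block.init_loop(STEP_CATEGORY + ".", step_tags)
    for i, (step, asg, params) in enumerate(assignments, start=1):
        loop.add_row([
            str(i), "1", step.residue_1.chain_id,
            step.residue_1.seq_id, step.residue_1.comp_id,
            step.residue_2.seq_id, step.residue_2.comp_id,
            asg.ntc, asg.cana, _fmt(asg.confal, 1), _fmt(asg.rmsd, 4),
            *(_fmt(v, 4) for v in params.as_vector()),
        ])

    vg_tags = ["chain", "seq_id", "comp_id", "term_name", "term_type",
               "observed", "prosco", "zprime", "tier", "support"]
    loop = block.init_loop(VALGEOM_CATEGORY + ".", vg_tags)
    for v in verdicts:
        loop.add_row([
            v.chain_id, v.seq_id, v.comp_id, v.term_name, v.term_type,
            _fmt(v.observed, 4), _fmt(v.prosco, 2), _fmt(v.zprime, 3),
            v.tier, v.support,
        ])
    doc.write_file(str(path))


def _read_category(path, category: str) -> list[dict[str, str]]:
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    prefix = category + "."
    table = block.find_mmcif_category(prefix)
    if not table:
        return []
    tags = [t[len(prefix):] for t in table.tags]
    return [dict(zip(tags, list(row))) for row in table]


def read_step_table(path) -> list[dict[str, str]]:
    """Read back the ``_ntc_step`` category from an annotated mmCIF."""
    return _read_category(path, STEP_CATEGORY)


def read_valgeom_table(path) -> list[dict[str, str]]:
    """Read back the ``_ntc_valgeom`` category from an annotated mmCIF."""
    return _read_category(path, VALGEOM_CATEGORY)
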
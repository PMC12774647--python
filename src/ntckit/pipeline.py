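"""End-to-end annotation pipeline tying the modules together."""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import NtCTable, NANT_THRESHOLD, assign_ntc
from .model import Structure, extract_na_chains, resolve_altlocs
from .steps import CONNECTIVITY_CUTOFF, compute_step_parameters, find_steps

__all__ = ["AnnotationResult", "annotate_structure"]


@dataclass
class AnnotationResult:
    """Steps with assignments plus bookkeeping of skipped pairs."""

    records: list = field(default_factory=list)  # (step, StepAssignment, StepParameters)
    skipped: list = field(default_factory=list)  # (pair label, reason)

    @property
    def summary(self) -> dict:
        n_nant = sum(1 for _, a, _ in self.records if a.ntc == "NANT")
        by_reason: dict[str, int] = {}
        for _, reason in self.skipped:
            by_reason[reason] = by_reason.get(reason, 0) + 1
        return {
            "steps": len(self.records),
            "assigned": len(self.records) - n_nant,
            "nant": n_nant,
            "skipped": by_reason,
        }


def annotate_structure(
    structure: Structure,
    table: NtCTable,
    model_index: int = 0,
    altloc_policy: str = "highest_occupancy",
    altloc_label: str | None = None,
    connectivity_cutoff: float = CONNECTIVITY_CUTOFF,
    nant_threshold: float = NANT_THRESHOLD,
) -> AnnotationResult:
    """Resolve altlocs, detect steps and assign NtC classes for one model."""
    resolve_altlocs(structure, policy=altloc_policy, label=altloc_label)
    result = AnnotationResult()
    for chain in extract_na_chains(structure, model_index=model_index):
        for step in find_steps(chain, cutoff=connectivity_cutoff, skipped=result.skipped):
            params = compute_step_parameters(step)
            assignment = assign_ntc(step, params, table, nant_threshold=nant_threshold)
            result.records.append((step, assignment, params))
    return result
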
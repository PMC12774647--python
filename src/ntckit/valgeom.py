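"""Empirical valence-geometry validation of bond lengths and angles.

Every measurable bond/angle term of a nucleotide is compared against an
empirical reference distribution (emulating a curated high-resolution
reference set) and small-molecule (CSD-style) mean/sigma values:

* **ProSco** — a two-sided probability percentile score: the Hazen
  empirical-CDF position F of the observed value maps to
  200 * min(F, 1 - F), so ProSco >= 5 delimits the central 95% of the
  reference distribution.
* **Z'** — a non-parametric standard score, (x - median) / (1.4826 * MAD).
* **Tier** — Preferred when inside the union of the ProSco >= 5 interval
  and the CSD mean +/- 3 sigma interval (the more permissive boundary on
  each side); otherwise Allowed when |Z'| <= 5; otherwise Of Concern.
* **Support** — Common / Rare / Ambiguous / Unique, describing how many
  reference observations lie near the observed value.
* **Nearest reference cases** — the closest reference observations, for
  contextual inspection of flagged values.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.stats import median_abs_deviation

from .geometry import distance as _distance
from .geometry import planar_angle
from .model import Chain, Residue

logger = logging.getLogger("ntckit")

__all__ = [
    "GeometryTermDefinition",
    "ReferenceDistribution",
    "ValidationVerdict",
    "hazen_cdf",
    "hazen_percentile",
    "load_term_dictionary",
    "enumerate_terms",
    "prosco",
    "prosco_interval",
    "z_prime",
    "classify_tier",
    "annotate_support",
    "nearest_reference_cases",
    "validate_residue",
    "validate_chain",
    "load_distributions",
    "write_distributions",
]

#: MAD-to-sigma consistency constant for normal data
MAD_SCALE = 1.4826

#: |Z'| boundary between Allowed and Of Concern
Z_PRIME_LIMIT = 5.0

#: ProSco boundary of the central (Preferred-candidate) region
PROSCO_LIMIT = 5.0

#: default support-count windows (heuristic, configurable)
SUPPORT_WIN_BOND = 0.01  # angstroms
SUPPORT_WIN_ANGLE = 1.0  # degrees
SUPPORT_K_MIN = 3


@dataclass(frozen=True)
class GeometryTermDefinition:
    """One dictionary bond/angle term and the residue class it applies to."""

    term_name: str
    term_type: str  # "bond" | "angle"
    atom_names: tuple[str, ...]  # 2 or 3 labels; "p:" prefix = 5' neighbour
    applies_to: str

    def __post_init__(self) -> None:
        expected = 2 if self.term_type == "bond" else 3
        if len(self.atom_names) != expected:
            raise ValueError(f"{self.term_name}: {self.term_type} needs {expected} atoms")


@dataclass
class ReferenceDistribution:
    """Empirical sample plus small-molecule mean/sigma for one term."""

    term_name: str
    sample: np.ndarray  # sorted observed values
    case_ids: list[str]  # aligned with sample
    csd_mean: float
    csd_sigma: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.sample = np.asarray(self.sample, dtype=float)
        order = np.argsort(self.sample, kind="stable")
        self.sample = self.sample[order]
        self.case_ids = [self.case_ids[i] for i in order]
        if self.csd_sigma <= 0:
            raise ValueError(f"{self.term_name}: csd_sigma must be positive")

    @property
    def n(self) -> int:
        return int(self.sample.size)


@dataclass
class ValidationVerdict:
    """Per-term validation outcome for one residue."""

    chain_id: str
    seq_id: str
    comp_id: str
    term_name: str
    term_type: str
    observed: float
    prosco: float
    zprime: float
    tier: str  # Preferred | Allowed | OfConcern
    support: str  # Common | Rare | Ambiguous | Unique
    nearest_cases: list[tuple[str, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# empirical-CDF machinery (Hazen plotting positions)
# ---------------------------------------------------------------------------

def hazen_cdf(sorted_sample: np.ndarray, x):
    """Empirical CDF position of ``x``: Hazen convention (rank - 0.5)/n,
    linearly interpolated between order statistics, clamped to [0, 1]
    outside the sample range. Accepts a scalar or an array."""
    s = np.asarray(sorted_sample, dtype=float)
    n = s.size
    positions = (np.arange(1, n + 1) - 0.5) / n
    xa = np.asarray(x, dtype=float)
    f = np.interp(xa, s, positions)
    f = np.where(xa < s[0], 0.0, np.where(xa > s[-1], 1.0, f))
    return float(f) if np.isscalar(x) or xa.ndim == 0 else f


def hazen_percentile(sorted_sample: np.ndarray, q: float) -> float:
    """Inverse of :func:`hazen_cdf`: the value at CDF position ``q``."""
    s = np.asarray(sorted_sample, dtype=float)
    n = s.size
    positions = (np.arange(1, n + 1) - 0.5) / n
    return float(np.interp(q, positions, s))


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def prosco(x, d: ReferenceDistribution):
    """Two-sided percentile score in [0, 100]; >= 5 marks the central 95%.

    Accepts a scalar or an array of observed values.
    """
    if d.n < 20:
        raise ValueError(f"{d.term_name}: sample too small for validation (n={d.n} < 20)")
    f = hazen_cdf(d.sample, x)
    score = np.clip(200.0 * np.minimum(f, 1.0 - f), 0.0, 100.0)
    return float(score) if np.ndim(score) == 0 else score


def prosco_interval(d: ReferenceDistribution) -> tuple[float, float]:
    """The ProSco >= 5 interval: the [2.5th, 97.5th] Hazen percentiles."""
    return hazen_percentile(d.sample, 0.025), hazen_percentile(d.sample, 0.975)


def z_prime(x: float, d: ReferenceDistribution) -> float:
    """Robust standard score (x - median) / (1.4826 * MAD)."""
    med = float(np.median(d.sample))
    mad = float(median_abs_deviation(d.sample))
    if mad <= 0:
        raise ValueError(f"{d.term_name}: zero spread, Z' undefined")
    return (x - med) / (MAD_SCALE * mad)


def classify_tier(x: float, d: ReferenceDistribution, z_limit: float = Z_PRIME_LIMIT) -> str:
    """Three-tier verdict: Preferred / Allowed / OfConcern.

    The Preferred interval is the union of the ProSco >= 5 interval and
    the CSD mean +/- 3 sigma interval — the more permissive of the two
    boundaries on each side, accommodating differences between
    macromolecular and small-molecule environments.
    """
    lo_p, hi_p = prosco_interval(d)
    lo = min(lo_p, d.csd_mean - 3.0 * d.csd_sigma)
    hi = max(hi_p, d.csd_mean + 3.0 * d.csd_sigma)
    if lo <= x <= hi:
        return "Preferred"
    if abs(z_prime(x, d)) <= z_limit:
        return "Allowed"
    return "OfConcern"


def _default_win(term: str | GeometryTermDefinition) -> float:
    if isinstance(term, GeometryTermDefinition):
        return SUPPORT_WIN_BOND if term.term_type == "bond" else SUPPORT_WIN_ANGLE
    # infer from the term label: two atoms -> bond, three -> angle
    return SUPPORT_WIN_BOND if term.count("-") <= 1 else SUPPORT_WIN_ANGLE


def annotate_support(
    x: float,
    p: float,
    d: ReferenceDistribution,
    win: float | None = None,
    k_min: int = SUPPORT_K_MIN,
) -> str:
    """Support category of a validated value: how well the reference
    distribution populates its neighbourhood.

    k = number of reference values within +/- win of x. Unique when
    k = 0; Common when ProSco >= 5; Rare when k >= k_min; else Ambiguous.
    The window defaults to 0.01 A for bonds and 1.0 degree for angles.
    """
    if win is None:
        win = _default_win(d.term_name)
    k = int(np.sum(np.abs(d.sample - x) <= win))
    if k == 0:
        return "Unique"
    if p >= PROSCO_LIMIT:
        return "Common"
    if k >= k_min:
        return "Rare"
    return "Ambiguous"


def nearest_reference_cases(x: float, d: ReferenceDistribution, k: int) -> list[tuple[str, float]]:
    """The k reference cases closest in value to x, ties by case id."""
    if k <= 0:
        raise ValueError("k must be positive")
    ranked = sorted(zip(d.case_ids, d.sample), key=lambda cv: (abs(cv[1] - x), cv[0]))
    return [(cid, float(v)) for cid, v in ranked[:k]]


# ---------------------------------------------------------------------------
# term dictionary + measurement
# ---------------------------------------------------------------------------

def load_term_dictionary(path=None) -> list[GeometryTermDefinition]:
    """Load the bond/angle term dictionary (packaged one by default).

    The packaged dictionary covers the five canonical bases, the
    ribose/deoxyribose sugar and the phosphodiester linkage, using
    standard atom nomenclature; authoritative dictionaries can be
    dropped in via the same CSV schema.
    """
    if path is None:
        ctx = resources.files("ntckit.data").joinpath("geometry_terms.csv").open()
    else:
        ctx = open(path)
    terms = []
    with ctx as fh:
        for row in csv.DictReader(fh):
            atoms = tuple(a for a in (row["atom1"], row["atom2"], row.get("atom3", "")) if a)
            terms.append(GeometryTermDefinition(
                term_name=row["term_name"],
                term_type=row["term_type"],
                atom_names=atoms,
                applies_to=row["applies_to"],
            ))
    return terms


_BASE_GROUP = {"A": "A", "DA": "A", "G": "G", "DG": "G",
               "C": "C", "DC": "C", "U": "U", "DU": "U", "DT": "T"}


def _residue_groups(res: Residue, has_prev: bool) -> set[str]:
    groups = {"all"}
    if res.moiety_class == "ribonucleotide":
        groups.add("ribose")
    groups.add("purine" if res.is_purine else "pyrimidine")
    base = _BASE_GROUP.get(res.parent_comp)
    if base:
        groups.add(base)
    if has_prev:
        groups.add("linkage")
    return groups


def enumerate_terms(
    residue: Residue,
    dictionary: list[GeometryTermDefinition] | None = None,
    prev_residue: Residue | None = None,
) -> list[tuple[GeometryTermDefinition, float]]:
    """Measure every applicable dictionary term on a residue.

    Bonds are measured as distances, angles via the interior planar
    angle. Terms whose atoms are not all present are skipped with a log
    message. Phosphodiester linkage terms (atom labels prefixed "p:")
    are measured only when the 5' neighbour is supplied.
    """
    if dictionary is None:
        dictionary = load_term_dictionary()
    groups = _residue_groups(residue, prev_residue is not None)
    out = []
    for term in dictionary:
        if term.applies_to not in groups:
            continue
        positions = []
        missing = False
        for label in term.atom_names:
            res = residue
            name = label
            if label.startswith("p:"):
                res = prev_residue
                name = label[2:]
            atom = res.atom(name) if res is not None else None
            if atom is None:
                missing = True
                break
            positions.append(atom.position)
        if missing:
            logger.info("term %s skipped on %s: missing atoms", term.term_name, residue.label)
            continue
        if term.term_type == "bond":
            value = _distance(positions[0], positions[1])
        else:
            value = planar_angle(*positions)
        out.append((term, value))
    return out


def validate_residue(
    residue: Residue,
    distributions: dict[str, ReferenceDistribution],
    dictionary: list[GeometryTermDefinition] | None = None,
    prev_residue: Residue | None = None,
    n_nearest: int = 3,
) -> list[ValidationVerdict]:
    """Full validation of one residue: measure, score, classify.

    Terms without a reference distribution are skipped with a warning.
    """
    verdicts = []
    for term, observed in enumerate_terms(residue, dictionary, prev_residue):
        d = distributions.get(term.term_name)
        if d is None:
            logger.warning("no reference distribution for %s; term skipped", term.term_name)
            continue
        p = prosco(observed, d)
        verdicts.append(ValidationVerdict(
            chain_id=residue.chain_id,
            seq_id=residue.seq_id,
            comp_id=residue.comp_id,
            term_name=term.term_name,
            term_type=term.term_type,
            observed=observed,
            prosco=p,
            zprime=z_prime(observed, d),
            tier=classify_tier(observed, d),
            support=annotate_support(observed, p, d, win=_default_win(term)),
            nearest_cases=nearest_reference_cases(observed, d, n_nearest),
        ))
    return verdicts


def validate_chain(
    chain: Chain,
    distributions: dict[str, ReferenceDistribution],
    dictionary: list[GeometryTermDefinition] | None = None,
    connectivity_cutoff: float = 2.0,
) -> list[ValidationVerdict]:
    """Validate every residue of a chain, including linkage terms for
    covalently continuous residue pairs."""
    if dictionary is None:
        dictionary = load_term_dictionary()
    verdicts = []
    prev: Residue | None = None
    for res in chain.residues:
        linked = None
        if prev is not None:
            o3 = prev.atom("O3'")
            p = res.atom("P")
            if o3 is not None and p is not None and _distance(o3.position, p.position) <= connectivity_cutoff:
                linked = prev
        verdicts.extend(validate_residue(res, distributions, dictionary, prev_residue=linked))
        prev = res
    return verdicts


# ---------------------------------------------------------------------------
# distribution file I/O
# ---------------------------------------------------------------------------

def write_distributions(dists: dict[str, ReferenceDistribution], sample_csv, csd_csv) -> None:
    """Write distributions as the two-file CSV layout (sample + CSD stats)."""
    with open(sample_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["term_name", "case_id", "value"])
        for d in dists.values():
            for cid, v in zip(d.case_ids, d.sample):
                w.writerow([d.term_name, cid, f"{v:.6f}"])
    with open(csd_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["term_name", "csd_mean", "csd_sigma", "provenance"])
        for d in dists.values():
            w.writerow([d.term_name, f"{d.csd_mean:.6f}", f"{d.csd_sigma:.6f}", d.provenance])


def load_distributions(sample_csv, csd_csv) -> dict[str, ReferenceDistribution]:
    """Read distributions back from the two-file CSV layout."""
    samples: dict[str, list[tuple[str, float]]] = {}
    with open(sample_csv) as fh:
        for row in csv.DictReader(fh):
            samples.setdefault(row["term_name"], []).append((row["case_id"], float(row["value"])))
    stats: dict[str, tuple[float, float, str]] = {}
    with open(csd_csv) as fh:
        for row in csv.DictReader(fh):
            stats[row["term_name"]] = (
                float(row["csd_mean"]), float(row["csd_sigma"]), row.get("provenance", ""),
            )
    out = {}
    for term, pairs in samples.items():
        if term not in stats:
            raise ValueError(f"{term}: sample present but no CSD stats")
        mean, sigma, prov = stats[term]
        out[term] = ReferenceDistribution(
            term_name=term,
            sample=np.array([v for _, v in pairs]),
            case_ids=[cid for cid, _ in pairs],
            csd_mean=mean,
            csd_sigma=sigma,
            provenance=prov,
        )
    return out
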
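"""Molecular-alteration analysis of biallelic variants on a large AAA-ATPase.

Localizes variants on a domain map of the protein (six AAA modules, a long
linker and a C-terminal MIDAS domain), tests the biallelic subregional
pattern (one allele in AAA2–AAA3, the other in the linker or its vicinity),
assesses hydrophobicity changes on the Fauchère–Pliska octanol–water scale,
classifies predicted stability changes (DDG), and assembles the per-variant
/ per-case characteristic point score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .models import AnnotationRecord, Variant

#: Fauchère–Pliska side-chain hydrophobicity (octanol–water partition, pi
#: values); higher = more hydrophobic.
FAUCHERE_PLISKA = {
    "W": 2.25, "I": 1.80, "F": 1.79, "L": 1.70, "C": 1.54, "M": 1.23,
    "V": 1.22, "Y": 0.96, "P": 0.72, "A": 0.31, "T": 0.26, "H": 0.13,
    "G": 0.00, "S": -0.04, "Q": -0.22, "N": -0.60, "E": -0.64, "D": -0.77,
    "K": -0.99, "R": -1.01,
}

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}


def one_letter(aa: str) -> str:
    """Accept one- or three-letter amino-acid codes."""
    if len(aa) == 1:
        return aa.upper()
    return _THREE_TO_ONE[aa.capitalize()]


@dataclass
class HydrophobicityScale:
    """Per-residue hydrophobicity values plus a three-way category partition.

    ``alteration_mode``: ``threshold`` flags a substitution whose
    |delta| >= ``delta_threshold`` (default 1.0 scale units); ``category``
    flags any substitution crossing category boundaries.
    """

    values: dict[str, float] = field(default_factory=lambda: dict(FAUCHERE_PLISKA))
    categories: dict[str, str] = field(default_factory=dict)
    alteration_mode: str = "threshold"
    delta_threshold: float = 1.0

    def __post_init__(self) -> None:
        if set(self.values) != set(FAUCHERE_PLISKA):
            missing = set(FAUCHERE_PLISKA) - set(self.values)
            raise ValueError(f"scale must cover all 20 residues; missing {sorted(missing)}")
        if not self.categories:
            self.categories = {
                aa: ("hydrophobic" if v >= 0.72 else "neutral" if v >= -0.30 else "hydrophilic")
                for aa, v in self.values.items()
            }
        if self.alteration_mode not in ("threshold", "category"):
            raise ValueError(f"unknown alteration_mode {self.alteration_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HydrophobicityScale":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            values=cfg.get("values", dict(FAUCHERE_PLISKA)),
            categories=cfg.get("categories", {}),
            alteration_mode=cfg.get("alteration_mode", "threshold"),
            delta_threshold=float(cfg.get("delta_threshold", 1.0)),
        )


def hydrophobicity_assessment(
    ref_aa: str, alt_aa: str, scale: Optional[HydrophobicityScale] = None
) -> tuple[float, bool]:
    """Hydrophobicity delta (alt − ref) and whether it counts as altered."""
    scale = scale or HydrophobicityScale()
    ra, aa = one_letter(ref_aa), one_letter(alt_aa)
    if ra not in scale.values or aa not in scale.values:
        raise ValueError(f"residue outside scale: {ref_aa!r} or {alt_aa!r}")
    delta = scale.values[aa] - scale.values[ra]
    if scale.alteration_mode == "threshold":
        altered = abs(delta) >= scale.delta_threshold
    else:
        altered = scale.categories[ra] != scale.categories[aa]
    return delta, altered


# ---------------------------------------------------------------------------
# Domain map
# ---------------------------------------------------------------------------

@dataclass
class DomainMap:
    """Ordered non-overlapping residue intervals on the protein.

    Residues outside every interval map to ``inter-domain``; positions within
    ``vicinity_window`` residues of the linker interval additionally carry a
    ``linker-vicinity`` mark.
    """

    protein_length: int = 5696
    intervals: list[tuple[str, int, int]] = field(default_factory=list)
    vicinity_window: int = 100

    def __post_init__(self) -> None:
        ordered = sorted(self.intervals, key=lambda iv: iv[1])
        prev_end = 0
        for label, start, end in ordered:
            if start < 1 or end > self.protein_length or start > end:
                raise ValueError(f"interval {label} [{start},{end}] outside protein")
            if start <= prev_end:
                raise ValueError(f"interval {label} overlaps its predecessor")
            prev_end = end
        self.intervals = ordered

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DomainMap":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            protein_length=int(cfg.get("protein_length", 5696)),
            intervals=[(d["label"], int(d["start"]), int(d["end"])) for d in cfg.get("intervals", [])],
            vicinity_window=int(cfg.get("vicinity_window", 100)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "protein_length": self.protein_length,
                    "vicinity_window": self.vicinity_window,
                    "intervals": [
                        {"label": l, "start": s, "end": e} for l, s, e in self.intervals
                    ],
                },
                sort_keys=False,
            )
        )


def default_domain_map() -> DomainMap:
    """Shipped default map for the 5696-residue reference protein.

    The residue boundaries are a synthetic, clearly-versioned configuration
    consistent with the protein's architecture (an N-terminal ring of six
    AAA modules, a long linker, a C-terminal MIDAS domain); they are *not* a
    published annotation, and boundary-dependent results should always be
    reported together with the map used.
    """
    return DomainMap(
        protein_length=5696,
        intervals=[
            ("AAA1", 211, 660),
            ("AAA2", 661, 960),
            ("AAA3", 961, 1310),
            ("AAA4", 1311, 1650),
            ("AAA5", 1651, 1990),
            ("AAA6", 1991, 2320),
            ("linker", 2321, 4770),
            ("MIDAS", 5596, 5696),
        ],
        vicinity_window=100,
    )


AAA_LABELS = frozenset({"AAA1", "AAA2", "AAA3", "AAA4", "AAA5", "AAA6"})


def locate_in_domain(protein_pos: int, domain_map: DomainMap) -> tuple[str, bool]:
    """Region label covering *protein_pos* plus a linker-vicinity mark.

    Returns ``(label, in_linker_vicinity)``; label is ``inter-domain`` when
    no interval covers the position.  Interval boundaries are inclusive.
    """
    if not (1 <= protein_pos <= domain_map.protein_length):
        raise ValueError(
            f"position {protein_pos} outside protein [1, {domain_map.protein_length}]"
        )
    label = "inter-domain"
    for lab, start, end in domain_map.intervals:
        if start <= protein_pos <= end:
            label = lab
            break
    vicinity = False
    for lab, start, end in domain_map.intervals:
        if lab == "linker":
            if (start - domain_map.vicinity_window <= protein_pos < start) or (
                end < protein_pos <= end + domain_map.vicinity_window
            ):
                vicinity = True
    return label, vicinity


def _localized_position(variant: Variant, annotation: Optional[AnnotationRecord]) -> Optional[int]:
    if variant.protein_pos is not None:
        return variant.protein_pos
    if annotation is not None and annotation.splice_residue is not None:
        return annotation.splice_residue
    return None


def biallelic_subregional_pattern(
    variant_a: Variant,
    variant_b: Variant,
    domain_map: Optional[DomainMap] = None,
    annotations: Optional[dict] = None,
) -> bool:
    """True iff one member lies in AAA2/AAA3 and the other in the linker or
    its vicinity (order-independent).  Splice variants localize through the
    annotated residue of the exon boundary they abut."""
    domain_map = domain_map or default_domain_map()
    annotations = annotations or {}
    locs = []
    for v in (variant_a, variant_b):
        pos = _localized_position(v, annotations.get(v.key))
        if pos is None:
            return False
        locs.append(locate_in_domain(pos, domain_map))

    def in_aaa23(loc):
        return loc[0] in ("AAA2", "AAA3")

    def in_linkerish(loc):
        return loc[0] == "linker" or loc[1]

    (la, lb) = locs
    return (in_aaa23(la) and in_linkerish(lb)) or (in_aaa23(lb) and in_linkerish(la))


# ---------------------------------------------------------------------------
# Stability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilityThresholds:
    """DDG (kcal/mol) classification bounds: strictly above ``stabilizing_min``
    enhances stability, strictly below ``destabilizing_max`` reduces it."""

    stabilizing_min: float = 0.5
    destabilizing_max: float = -0.5


def stability_class(ddg: float, thresholds: Optional[StabilityThresholds] = None) -> str:
    thresholds = thresholds or StabilityThresholds()
    if ddg > thresholds.stabilizing_min:
        return "stabilizing"
    if ddg < thresholds.destabilizing_max:
        return "destabilizing"
    return "neutral"


# ---------------------------------------------------------------------------
# Characteristic point score
# ---------------------------------------------------------------------------

#: coding classes that earn the variant-type point (missense earns none;
#: splice-with-length-effect takes the 5-point path instead)
TYPE_POINT_CONSEQUENCES = frozenset({"nonsense", "frameshift", "inframe_indel", "initiation_codon"})

SPLICE_LENGTH_POINTS = 5


@dataclass
class ScoreBreakdown:
    variant: Variant
    subregional_effect: bool = False
    hbond_change: bool = False
    hydrophobicity_alteration: bool = False
    ddg_destabilizing: bool = False
    variant_type_point: bool = False
    splice_length_effect: bool = False
    #: per-bond mode only: number of altered hydrogen bonds counted
    hbond_points: int = 0

    @property
    def total(self) -> int:
        if self.splice_length_effect:
            return SPLICE_LENGTH_POINTS
        return (
            int(self.subregional_effect)
            + (self.hbond_points if self.hbond_points else int(self.hbond_change))
            + int(self.hydrophobicity_alteration)
            + int(self.ddg_destabilizing)
            + int(self.variant_type_point)
        )


def variant_characteristic_score(
    annotation: AnnotationRecord,
    domain_map: Optional[DomainMap] = None,
    scale: Optional[HydrophobicityScale] = None,
    thresholds: Optional[StabilityThresholds] = None,
    hbond_per_bond: bool = False,
) -> ScoreBreakdown:
    """Score one variant: 1 point per altered characteristic (AAA-domain
    location, any hydrogen-bond change, hydrophobicity alteration,
    destabilizing DDG, qualifying variant type); a splice variant that may
    affect protein length scores a flat 5."""
    domain_map = domain_map or default_domain_map()
    v = annotation.variant
    breakdown = ScoreBreakdown(variant=v)
    if v.consequence == "canonical_splice" and annotation.splice_length_effect:
        breakdown.splice_length_effect = True
        return breakdown
    pos = _localized_position(v, annotation)
    if pos is not None:
        label, _ = locate_in_domain(pos, domain_map)
        breakdown.subregional_effect = label in AAA_LABELS
    if annotation.hbond_changes:
        breakdown.hbond_change = True
        if hbond_per_bond:
            breakdown.hbond_points = annotation.hbond_changes
    if v.consequence == "missense" and v.ref_aa and v.alt_aa:
        _, altered = hydrophobicity_assessment(v.ref_aa, v.alt_aa, scale)
        breakdown.hydrophobicity_alteration = altered
    if annotation.ddg is not None:
        breakdown.ddg_destabilizing = stability_class(annotation.ddg, thresholds) == "destabilizing"
    if v.consequence in TYPE_POINT_CONSEQUENCES:
        breakdown.variant_type_point = True
    return breakdown


@dataclass
class CaseScore:
    case_id: str
    breakdowns: list[ScoreBreakdown]

    @property
    def total(self) -> int:
        return sum(b.total for b in self.breakdowns)


def case_severity_score(per_case: dict[str, Iterable[ScoreBreakdown]]) -> list[CaseScore]:
    """Sum pair-member scores per case; sorted total-descending with a
    deterministic tie-break by case id."""
    scores = [CaseScore(cid, list(bs)) for cid, bs in per_case.items()]
    return sorted(scores, key=lambda s: (-s.total, s.case_id))
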
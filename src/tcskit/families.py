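"""Rule-based assignment of proteins to two-component-system families.

A protein's family is determined by its ordered domain composition: a CHASE
domain marks a cytokinin receptor (CHK), an ethylene-binding domain plus GAF
an ethylene receptor (ETR), a histidine-kinase domain without either a
non-receptor kinase (HK), a sole Hpt domain a phosphotransfer protein (HPT),
and a receiver domain combined with Myb / CCT / nothing a Type-B, clock, or
Type-A/C response regulator respectively.  The rules fire in priority
order and exactly one (or none) applies to each protein.

Canonicity then requires the full complement of functional motifs: the
phospho-accepting H in the H-box, the N/G1/F/G2 ATPase boxes, and the
conserved phosphoacceptor D (H for HPTs) in the receiver (Hpt) domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .align import align_global
from .seqio import DomainHit, GeneLocus, ProteinRecord

__all__ = [
    "DomainArchitecture",
    "TCSCall",
    "classify_family",
    "assign_nearest_reference",
    "assign_nomenclature",
    "FAMILIES",
]

FAMILIES = ("CHK", "HK", "ETR", "HPT", "RRA", "RRB", "RRC", "clock-RR",
            "unclassified")

_KINASE_BOXES = ("N", "G1", "F", "G2")
SHORT_CTER_AA = 100  # transactivation domains shorter than this are flagged


@dataclass
class DomainArchitecture:
    """Ordered domain hits on one protein.

    Hits are kept sorted by start; overlapping hits of the same domain are
    merged (union of spans, best e-value, merged motif states).
    """

    hits: list[DomainHit] = field(default_factory=list)
    protein_length: int = 0

    def __post_init__(self) -> None:
        self.hits = _merge_same_name(sorted(
            self.hits, key=lambda h: (h.start, h.end, h.domain_name)))

    def has(self, name: str) -> bool:
        return any(h.domain_name == name for h in self.hits)

    def get(self, name: str) -> DomainHit | None:
        for h in self.hits:
            if h.domain_name == name:
                return h
        return None

    def motif(self, domain: str, label: str) -> str:
        """State of a motif: residue letter, '+', '-' (absent) or '?'."""
        hit = self.get(domain)
        if hit is None:
            return "-"
        return hit.motif_states.get(label, "?")

    def summary(self) -> str:
        parts = []
        for h in self.hits:
            if h.motif_states:
                states = ",".join(v for v in h.motif_states.values())
                parts.append(f"{h.domain_name}({states})")
            else:
                parts.append(h.domain_name)
        return " ".join(parts)


def _merge_same_name(hits: list[DomainHit]) -> list[DomainHit]:
    merged: list[DomainHit] = []
    for h in hits:
        if merged and merged[-1].domain_name == h.domain_name \
                and h.start <= merged[-1].end + 1:
            prev = merged[-1]
            prev.end = max(prev.end, h.end)
            prev.evalue = min(prev.evalue, h.evalue)
            for k, v in h.motif_states.items():
                prev.motif_states.setdefault(k, v)
        else:
            merged.append(DomainHit(h.domain_name, h.start, h.end, h.evalue,
                                    dict(h.motif_states)))
    return merged


@dataclass
class TCSCall:
    """The classifier's verdict for one protein."""

    protein_id: str
    family: str
    canonical: bool = False
    truncated: bool = False
    short_cter: bool = False
    name: str = ""
    length: int = 0
    nearest_reference: str = ""
    variant_class: str = ""
    notes: str = ""
    domain_summary: str = ""

    def __post_init__(self) -> None:
        if self.family == "unclassified" and self.canonical:
            raise ValueError("an unclassified protein cannot be canonical")
        if self.canonical and self.truncated:
            raise ValueError("a canonical protein cannot be truncated")


def _receiver_residue(arch: DomainArchitecture) -> str:
    return arch.motif("Rec", "D")


def _kinase_core_ok(arch: DomainArchitecture) -> bool:
    if arch.motif("His", "H") != "H":
        return False
    if not arch.has("HATPase_c"):
        return False
    return all(arch.motif("HATPase_c", b) in ("+", b)
               for b in _KINASE_BOXES)


@dataclass(frozen=True)
class FamilyRule:
    """One membership rule: first matching rule (by priority) fires."""

    family: str
    required: tuple[str, ...] = ()
    required_any: tuple[str, ...] = ()
    forbidden: tuple[str, ...] = ()
    variant: str = ""
    priority: int = 0

    def matches(self, arch: "DomainArchitecture") -> bool:
        if any(arch.has(d) for d in self.forbidden):
            return False
        if self.required and not all(arch.has(d) for d in self.required):
            return False
        if self.required_any and not any(arch.has(d)
                                         for d in self.required_any):
            return False
        return True


def load_family_rules() -> list[FamilyRule]:
    """Load the packaged (editable) family-membership rule table."""
    import yaml
    from importlib import resources

    path = resources.files("tcskit.data") / "family_rules.yaml"
    with path.open() as fh:
        data = yaml.safe_load(fh)
    rules = []
    for i, raw in enumerate(data["rules"]):
        rules.append(FamilyRule(
            family=raw["family"],
            required=tuple(raw.get("required", ())),
            required_any=tuple(raw.get("required_any", ())),
            forbidden=tuple(raw.get("forbidden", ())),
            variant=raw.get("variant", ""),
            priority=i,
        ))
    return rules


_RULES: list[FamilyRule] | None = None


def _rules() -> list[FamilyRule]:
    global _RULES
    if _RULES is None:
        _RULES = load_family_rules()
    return _RULES


def match_family(arch: "DomainArchitecture") -> FamilyRule | None:
    """First rule of the packaged rule table matching the architecture."""
    for rule in _rules():
        if rule.matches(arch):
            return rule
    return None


def classify_family(arch: DomainArchitecture,
                    protein_id: str = "") -> TCSCall:
    """Classify a protein into its family from its domain architecture.

    Family membership comes from the packaged priority-ordered rule table
    (``data/family_rules.yaml``); canonicity additionally requires every
    functional motif of the family, and missing domains set ``truncated``.
    Total function: an architecture matching no rule yields
    ``unclassified``.
    """
    rec = _receiver_residue(arch)
    has_rec = arch.has("Rec")
    rule = match_family(arch)
    family = rule.family if rule is not None else "unclassified"
    myb_less = rule is not None and rule.variant == "Myb-less"

    if family == "CHK":
        canonical = _kinase_core_ok(arch) and has_rec and rec == "D"
        return TCSCall(protein_id, "CHK", canonical=canonical,
                       truncated=not canonical,
                       variant_class="canonical" if canonical else "truncated",
                       domain_summary=arch.summary())
    if family == "ETR":
        # Ethylene receptors: receiver optional (ERS-type lacks it).
        canonical = _kinase_core_ok(arch) and has_rec and rec == "D"
        truncated = not (_kinase_core_ok(arch) and has_rec)
        return TCSCall(protein_id, "ETR", canonical=canonical,
                       truncated=truncated,
                       variant_class="canonical" if canonical
                       else ("ERS-type" if not has_rec else "degenerate-kinase"),
                       domain_summary=arch.summary())
    if family == "HK":
        canonical = _kinase_core_ok(arch) and has_rec and rec == "D"
        return TCSCall(protein_id, "HK", canonical=canonical,
                       truncated=not canonical,
                       variant_class="canonical" if canonical else "truncated",
                       domain_summary=arch.summary())
    if family == "HPT":
        residue = arch.motif("Hpt", "H")
        canonical = residue == "H"
        label = {"H": "HPT-H", "N": "HPT-N"}.get(
            residue, f"HPT-X({residue})" if residue not in "?-" else "HPT-?")
        return TCSCall(protein_id, "HPT", canonical=canonical,
                       variant_class=label, domain_summary=arch.summary())
    if family == "clock-RR":
        # Clock-related RRs carry E at the phosphoacceptor by construction.
        return TCSCall(protein_id, "clock-RR", canonical=(rec == "E"),
                       variant_class=f"Rec-{rec}",
                       domain_summary=arch.summary())
    if family == "RRB" and not myb_less:
        cter = arch.get("C-ter")
        cter_len = None
        if cter is not None and cter.motif_states.get("length"):
            cter_len = int(cter.motif_states["length"])
        short = cter_len is not None and cter_len < SHORT_CTER_AA
        canonical = rec == "D" and cter is not None
        variant = "canonical" if canonical else (
            f"D-to-{rec}" if rec in "EN" else f"other({rec})")
        return TCSCall(protein_id, "RRB", canonical=canonical,
                       short_cter=short, variant_class=variant,
                       domain_summary=arch.summary())
    if family == "RRB" and myb_less:
        # Receiver + transactivation without Myb: groups with the RRBs but
        # cannot act as a transcription factor (Myb-less RRB-like).
        variant = f"Myb-less(D-to-{rec})" if rec in "EN" else "Myb-less"
        return TCSCall(protein_id, "RRB", canonical=False,
                       variant_class=variant, domain_summary=arch.summary())
    if family == "RRA":
        # Sole receiver domain: Type-A by default; refined to RRC or
        # RRB-like by nearest-reference assignment when sequences exist.
        canonical = rec == "D"
        variant = "canonical" if canonical else (
            f"D-to-{rec}" if rec in "EN" else f"other({rec})")
        return TCSCall(protein_id, "RRA", canonical=canonical,
                       variant_class=variant, domain_summary=arch.summary())
    return TCSCall(protein_id, "unclassified", canonical=False,
                   domain_summary=arch.summary())


# ---------------------------------------------------------------------------
# Nearest-reference assignment

def assign_nearest_reference(
    protein: ProteinRecord,
    references: Sequence[ProteinRecord],
) -> tuple[str, float]:
    """Best-matching reference by normalized global-alignment score.

    The score is normalized by the self-score of the shorter sequence, so a
    reference aligned to itself scores exactly 1.0.  Used to place HKs into
    the AHK1/CKI1/CKI2 subclades, ETRs into ethylene-receptor subfamilies,
    and to disambiguate receiver-only proteins (Type-A vs Type-C vs
    Myb-less Type-B-like) against receiver exemplars.
    """
    if not references:
        raise ValueError("reference set is empty")
    from .align import _DEFAULT_MATRIX, _encode
    import numpy as np

    best_id, best_score = "", -np.inf
    for ref in references:
        shorter = protein if len(protein) <= len(ref) else ref
        self_score = float(
            _DEFAULT_MATRIX[np.ix_(_encode(shorter.sequence),
                                   _encode(shorter.sequence))]
            .diagonal().sum())
        score = align_global(protein, ref).score
        norm = score / self_score if self_score > 0 else 0.0
        if norm > best_score:
            best_id, best_score = ref.id, norm
    return best_id, best_score


# ---------------------------------------------------------------------------
# Nomenclature

def assign_nomenclature(
    calls: Sequence[TCSCall],
    alias_table: Mapping[str, str],
    loci: Iterable[GeneLocus] = (),
) -> list[TCSCall]:
    """Assign unified names: aliases are preserved, unnamed genes numbered.

    ``alias_table`` maps published names to unified names (e.g.
    ``CRE1 -> MtCHK1``); each alias must be unique.  Genes without an alias
    are numbered within their family, in chromosomal order (when loci are
    supplied, else input order), starting after the highest aliased number.
    """
    values = list(alias_table.values())
    if len(set(values)) != len(values):
        raise ValueError("alias table maps two published names to one name")

    order: dict[str, tuple] = {}
    for loc in loci:
        order[loc.gene_id] = (loc.chromosome, loc.start)

    import re

    def family_prefix(fam: str) -> str:
        return {"clock-RR": "MtPRR", "RRA": "MtRRA", "RRB": "MtRRB",
                "RRC": "MtRRC", "HPT": "MtHPT", "CHK": "MtCHK",
                "HK": "MtHK", "ETR": "MtETR"}.get(fam, "MtTCS")

    highest: dict[str, int] = {}
    named: list[TCSCall] = []
    for c in calls:
        alias = alias_table.get(c.protein_id) or alias_table.get(c.name)
        if alias:
            c = replace(c, name=alias)
        if c.name:
            m = re.match(rf"{family_prefix(c.family)}(\d+)$", c.name)
            if m:
                highest[c.family] = max(highest.get(c.family, 0),
                                        int(m.group(1)))
        named.append(c)

    unnamed = [c for c in named if not c.name]
    unnamed.sort(key=lambda c: order.get(c.protein_id, ("~", 0)))
    counters = dict(highest)
    result = {id(c): c for c in named}
    for c in unnamed:
        counters[c.family] = counters.get(c.family, 0) + 1
        result[id(c)] = replace(
            c, name=f"{family_prefix(c.family)}{counters[c.family]}")
    return [result[id(c)] for c in named]
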
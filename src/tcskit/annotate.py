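"""Sequence-path annotation: from domain hits to motif-resolved calls.

Domain tables (HMMER output) say where domains sit but not whether the
functional motifs inside them are intact.  This module resolves motif
states by aligning each protein to its family reference and projecting the
reference motif coordinates: the phospho-accepting H/D residues exactly,
and the kinase boxes (H-box, N, G1, F, G2) as consensus windows judged
present when at least 60% of the projected window matches the reference
consensus.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .align import GAP, align_global, project_position
from .families import (DomainArchitecture, TCSCall, assign_nearest_reference,
                       classify_family)
from .phosphosite import classify_variant, map_phosphoacceptor
from .references import ReferenceSet, default_references
from .seqio import DomainHit, ProteinRecord

__all__ = ["canonical_domain_name", "annotate_architecture", "classify_proteins"]

MOTIF_MATCH_FRACTION = 0.6

# HMMER/Pfam domain names -> the pipeline's canonical domain labels.
_PFAM_ALIASES = {
    "CHASE": "CHASE",
    "HisKA": "His",
    "His": "His",
    "HisKA_2": "His",
    "HATPase_c": "HATPase_c",
    "Response_reg": "Rec",
    "Rec": "Rec",
    "Hpt": "Hpt",
    "HPT": "Hpt",
    "Myb_DNA-binding": "Myb",
    "Myb": "Myb",
    "Myb_CC_LHEQLE": "Myb",
    "CCT": "CCT",
    "CCT_2": "CCT",
    "GAF": "GAF",
    "GAF_2": "GAF",
    "Ethylene_sensor": "EBD",
    "EBD": "EBD",
}


def canonical_domain_name(name: str) -> str:
    return _PFAM_ALIASES.get(name, name)


def _window_present(aln, window, target_seq: str) -> tuple[bool, str]:
    """Project a consensus window; (>=60% identity, key residue)."""
    matched = 0
    total = 0
    key_res = "-"
    for offset, ref_pos in enumerate(range(window.start, window.end + 1)):
        t = project_position(aln, ref_pos)
        total += 1
        if t is GAP:
            continue
        residue = target_seq[t - 1]
        if residue == window.consensus[offset]:
            matched += 1
        if window.key_position is not None and ref_pos == window.key_position:
            key_res = residue
    return (matched / total >= MOTIF_MATCH_FRACTION), key_res


def annotate_architecture(
    protein: ProteinRecord,
    hits: Sequence[DomainHit],
    refs: ReferenceSet | None = None,
) -> DomainArchitecture:
    """Build a motif-resolved architecture from raw domain hits.

    Kinase-domain motif boxes are judged by projection against the HK
    reference; phosphoacceptor residues (Hpt H, receiver D) by projection
    against the family identification reference.  A Myb-bearing protein
    additionally receives a ``C-ter`` pseudo-domain spanning the residues
    after the Myb domain (the transactivation region).
    """
    if refs is None:
        refs = default_references()
    canon = [
        DomainHit(canonical_domain_name(h.domain_name), h.start, h.end,
                  h.evalue, dict(h.motif_states))
        for h in hits
    ]
    arch = DomainArchitecture(hits=canon, protein_length=len(protein))

    his = arch.get("His")
    hat = arch.get("HATPase_c")
    if his is not None or hat is not None:
        aln = align_global(refs["AHK4_SYN"], protein)
        for window in refs.hk_motifs:
            present, key_res = _window_present(aln, window,
                                               protein.sequence)
            if window.label == "H":
                if his is not None:
                    his.motif_states["H"] = (
                        "H" if key_res == "H" and present else "-")
            elif hat is not None:
                hat.motif_states[window.label] = "+" if present else "-"

    rec = arch.get("Rec")
    if rec is not None:
        if arch.has("Myb"):
            ref = refs.identification["RRB"]
        elif arch.has("His") or arch.has("HATPase_c") or arch.has("CHASE") \
                or arch.has("EBD"):
            ref = refs.identification["HK"]
        else:
            ref = refs.identification["RRA"]
        residue, _ = map_phosphoacceptor(protein, ref)
        rec.motif_states["D"] = residue if residue != "-" else "-"

    hpt = arch.get("Hpt")
    if hpt is not None and not arch.has("His"):
        residue, _ = map_phosphoacceptor(protein, refs.identification["HPT"])
        hpt.motif_states["H"] = residue if residue != "-" else "-"

    myb = arch.get("Myb")
    if myb is not None:
        cter_len = max(0, len(protein) - myb.end)
        cter = DomainHit("C-ter", start=min(myb.end + 1, len(protein)),
                         end=len(protein))
        cter.motif_states["length"] = str(cter_len)
        arch = DomainArchitecture(hits=arch.hits + [cter],
                                  protein_length=len(protein))
    return arch


def classify_proteins(
    proteins: Sequence[ProteinRecord],
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    refs: ReferenceSet | None = None,
    with_nearest: bool = True,
) -> list[TCSCall]:
    """Annotate and classify a protein set; fill nearest references.

    Receiver-only calls are refined by nearest-reference assignment
    against the receiver exemplars: closest to the Type-A exemplar stays
    Type-A, closest to the Type-C exemplar becomes RRC, closest to the
    Type-B receiver exemplar becomes a Myb-less Type-B-like call.
    """
    if refs is None:
        refs = default_references()
    calls: list[TCSCall] = []
    for p in proteins:
        arch = annotate_architecture(p, hits_by_protein.get(p.id, ()), refs)
        call = classify_family(arch, protein_id=p.id)
        call.length = len(p)
        if not with_nearest:
            calls.append(call)
            continue
        if call.family in ("CHK", "HK"):
            ref_id, _ = assign_nearest_reference(
                p, [refs[r] for r in refs.hk_exemplars])
            call.nearest_reference = ref_id
        elif call.family == "ETR":
            ref_id, _ = assign_nearest_reference(
                p, [refs[r] for r in refs.etr_exemplars])
            call.nearest_reference = ref_id
        elif call.family == "RRA" and not arch.has("Myb"):
            ref_id, _ = assign_nearest_reference(
                p, [refs[r] for r in refs.receiver_exemplars])
            call.nearest_reference = ref_id
            if ref_id == "ARR22_SYN":
                call.family = "RRC"
                call.notes = "receiver-only, nearest Type-C exemplar"
            elif ref_id == "ARR1_SYN":
                call.family = "RRB"
                call.canonical = False
                call.notes = "receiver-only grouping with Type-B RRs"
                rec_res = arch.motif("Rec", "D")
                call.variant_class = (f"Myb-less(D-to-{rec_res})"
                                      if rec_res in "EN" else "Myb-less")
        elif call.family == "HPT":
            call.nearest_reference = refs.identification["HPT"].protein.id
        calls.append(call)
    return calls
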
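"""Synthetic stand-in reference proteins for projection and classification.

These are constructed sequences, not database entries: deterministic,
mutually homologous families of reference proteins carrying the documented
phosphoacceptor coordinates of the real references (H77 of the HPT
substitution-table reference, D64 and the comparison D192 of the Type-B RR
reference) and consensus motif windows (H-box, N/G1/F/G2 ATPase boxes) at
fixed positions.  They give the projection and classification machinery
realistic targets without shipping third-party sequence data; analyses of
real proteomes should substitute the corresponding curated references via
the same interfaces.

Everything here derives from one seeded RNG, so the reference set is
byte-identical across runs; the packaged copy lives in
``data/synthetic_references.fasta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phosphosite import PhosphoSiteReference
from .seqio import ProteinRecord

__all__ = ["MotifWindow", "ReferenceSet", "build_reference_set"]

_SEED = 20190514
# Background alphabet excludes H, N and D so the placed phosphoacceptor and
# comparison residues are the only occurrences of those letters.
_AA = "ACEFGIKLMPQRSTVWY"

# Coordinates (1-based) of the fixed features, kept in one place.
HPT_SITE = 77
HPT_OTHER_H = (12, 45, 103, 130)
RRB_SITE = 64
RRB_OTHER_D = (30, 110, 192, 225)
HK_HBOX = (138, 142)      # window; the phospho H sits at 140
HK_NBOX = (205, 209)
HK_G1BOX = (225, 229)
HK_FBOX = (250, 254)
HK_G2BOX = (270, 274)
HK_REC_D = 384            # D64 of the HK receiver domain (starts at 321)


@dataclass(frozen=True)
class MotifWindow:
    """A consensus window on a reference: label, 1-based span, consensus."""

    label: str
    start: int
    end: int
    consensus: str
    key_position: int | None = None  # absolute position of a key residue
    key_residue: str = ""


@dataclass
class ReferenceSet:
    """The packaged reference proteins plus their annotated coordinates."""

    proteins: dict[str, ProteinRecord]
    phosphosites: dict[str, PhosphoSiteReference]  # substitution tables
    identification: dict[str, PhosphoSiteReference] = field(
        default_factory=dict)  # residue identification, by family
    hk_motifs: list[MotifWindow] = field(default_factory=list)
    hk_exemplars: tuple[str, ...] = ()
    etr_exemplars: tuple[str, ...] = ()
    receiver_exemplars: tuple[str, ...] = ()
    domain_spans: dict[str, dict[str, tuple[int, int]]] = field(
        default_factory=dict)

    def __getitem__(self, key: str) -> ProteinRecord:
        return self.proteins[key]


def _random_seq(rng: np.random.Generator, n: int,
                alphabet: str = _AA) -> list[str]:
    return [alphabet[i] for i in rng.integers(0, len(alphabet), size=n)]


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            frozen: set[int] = frozenset()) -> str:
    """Point-mutate at per-site ``rate``; 1-based ``frozen`` positions kept."""
    out = list(seq)
    for i in range(len(out)):
        if (i + 1) in frozen:
            continue
        if rng.random() < rate:
            out[i] = _AA[rng.integers(0, len(_AA))]
    return "".join(out)


def _place(seq: list[str], positions: tuple[int, ...] | tuple[int],
           residue: str) -> None:
    for p in positions:
        seq[p - 1] = residue


def build_reference_set() -> ReferenceSet:
    """Construct the deterministic synthetic reference set."""
    rng = np.random.default_rng(_SEED)
    proteins: dict[str, ProteinRecord] = {}

    # --- HPT references (149 aa, no indels between homologs) -------------
    hpt = _random_seq(rng, 149)
    _place(hpt, (HPT_SITE,) + HPT_OTHER_H, "H")
    hpt3 = "".join(hpt)
    frozen_h = {HPT_SITE} | set(HPT_OTHER_H)
    proteins["MtHPT3_SYN"] = ProteinRecord("MtHPT3_SYN", hpt3,
                                           name="MtHPT3 stand-in")
    proteins["AHP1_SYN"] = ProteinRecord(
        "AHP1_SYN", _mutate(rng, hpt3, 0.25, frozen_h),
        name="AHP1 stand-in")
    proteins["OsttaHPT_SYN"] = ProteinRecord(
        "OsttaHPT_SYN", _mutate(rng, hpt3, 0.45, {HPT_SITE}),
        name="O. tauri HPT outgroup stand-in")

    # --- Receiver / response-regulator references -------------------------
    rec = _random_seq(rng, 120)
    _place(rec, (RRB_SITE, RRB_OTHER_D[0], RRB_OTHER_D[1]), "D")
    rec_block = "".join(rec)
    myb = "".join(_random_seq(rng, 60))
    cter = _random_seq(rng, 70)
    # comparison D positions beyond the receiver domain (e.g. D192)
    rrb3 = list(rec_block + myb + "".join(cter))
    _place(rrb3, (RRB_OTHER_D[2], RRB_OTHER_D[3]), "D")
    rrb3_seq = "".join(rrb3)  # 250 aa; Rec 1..120, Myb 121..180, C-ter 181..250
    frozen_d = {RRB_SITE} | set(RRB_OTHER_D)
    proteins["MtRRB3_SYN"] = ProteinRecord("MtRRB3_SYN", rrb3_seq,
                                           name="MtRRB3 stand-in")
    proteins["ARR1_SYN"] = ProteinRecord(
        "ARR1_SYN", _mutate(rng, rrb3_seq, 0.25, frozen_d),
        name="ARR1 stand-in")
    arr6 = _mutate(rng, rec_block, 0.25, {RRB_SITE, RRB_OTHER_D[0],
                                          RRB_OTHER_D[1]})
    arr6 += "".join(_random_seq(rng, 55))
    proteins["ARR6_SYN"] = ProteinRecord("ARR6_SYN", arr6,
                                         name="ARR6 stand-in")
    arr22 = _mutate(rng, rec_block, 0.40, {RRB_SITE})
    arr22 += "".join(_random_seq(rng, 20))
    proteins["ARR22_SYN"] = ProteinRecord("ARR22_SYN", arr22,
                                          name="ARR22 stand-in")

    # --- Histidine-kinase references --------------------------------------
    chase = _random_seq(rng, 100)
    linker1 = _random_seq(rng, 20)
    hiska = _random_seq(rng, 65)
    linker2 = _random_seq(rng, 5)
    hatpase = _random_seq(rng, 110)
    linker3 = _random_seq(rng, 20)
    rec_hk = _random_seq(rng, 90)
    ahk4 = chase + linker1 + hiska + linker2 + hatpase + linker3 + rec_hk
    # motif boxes (literal consensus = the reference residues)
    _place(ahk4, (140,), "H")
    _place(ahk4, (HK_NBOX[0],), "N")
    _place(ahk4, (HK_G1BOX[0],), "G")
    _place(ahk4, (HK_FBOX[0],), "F")
    _place(ahk4, (HK_G2BOX[0],), "G")
    _place(ahk4, (HK_REC_D,), "D")
    ahk4_seq = "".join(ahk4)  # 410 aa
    motif_positions = set()
    for lo, hi in (HK_HBOX, HK_NBOX, HK_G1BOX, HK_FBOX, HK_G2BOX):
        motif_positions.update(range(lo, hi + 1))
    frozen_hk = motif_positions | {HK_REC_D}
    proteins["AHK4_SYN"] = ProteinRecord("AHK4_SYN", ahk4_seq,
                                         name="AHK4/CRE1 stand-in")
    proteins["AHK2_SYN"] = ProteinRecord(
        "AHK2_SYN", _mutate(rng, ahk4_seq, 0.25, frozen_hk),
        name="AHK2 stand-in")
    proteins["AHK3_SYN"] = ProteinRecord(
        "AHK3_SYN", _mutate(rng, ahk4_seq, 0.25, frozen_hk),
        name="AHK3 stand-in")
    # non-CHASE kinases: same kinase core, no CHASE domain
    core = ahk4_seq[120:]
    core_frozen = {p - 120 for p in frozen_hk}
    for name, label in (("AHK1_SYN", "AHK1 osmosensor stand-in"),
                        ("CKI1_SYN", "CKI1 stand-in"),
                        ("CKI2_SYN", "CKI2/AHK5 stand-in")):
        proteins[name] = ProteinRecord(
            name, _mutate(rng, core, 0.25, core_frozen), name=label)
    # ethylene receptor: EBD + GAF + kinase core
    ebd = "".join(_random_seq(rng, 90))
    gaf = "".join(_random_seq(rng, 60))
    proteins["ETR1_SYN"] = ProteinRecord(
        "ETR1_SYN", ebd + gaf + _mutate(rng, core, 0.25, core_frozen),
        name="ETR1 stand-in")

    hk_motifs = [
        MotifWindow("H", HK_HBOX[0], HK_HBOX[1],
                    ahk4_seq[HK_HBOX[0] - 1:HK_HBOX[1]],
                    key_position=140, key_residue="H"),
        MotifWindow("N", HK_NBOX[0], HK_NBOX[1],
                    ahk4_seq[HK_NBOX[0] - 1:HK_NBOX[1]]),
        MotifWindow("G1", HK_G1BOX[0], HK_G1BOX[1],
                    ahk4_seq[HK_G1BOX[0] - 1:HK_G1BOX[1]]),
        MotifWindow("F", HK_FBOX[0], HK_FBOX[1],
                    ahk4_seq[HK_FBOX[0] - 1:HK_FBOX[1]]),
        MotifWindow("G2", HK_G2BOX[0], HK_G2BOX[1],
                    ahk4_seq[HK_G2BOX[0] - 1:HK_G2BOX[1]]),
    ]

    phosphosites = {
        "HPT": PhosphoSiteReference(
            "HPT", proteins["MtHPT3_SYN"], HPT_SITE, "H",
            comparison_positions=list(HPT_OTHER_H)),
        "RRB": PhosphoSiteReference(
            "RRB", proteins["MtRRB3_SYN"], RRB_SITE, "D",
            comparison_positions=list(RRB_OTHER_D)),
        "RRA": PhosphoSiteReference(
            "RRA", proteins["ARR6_SYN"], RRB_SITE, "D"),
        "HK": PhosphoSiteReference(
            "HK", proteins["AHK4_SYN"], HK_REC_D, "D"),
    }
    # Residue *identification* uses the functionally documented exemplars
    # (AHP1/ARR1/ARR6/AHK4 stand-ins); the substitution tables above use
    # the in-genome references.
    identification = {
        "HPT": PhosphoSiteReference("HPT", proteins["AHP1_SYN"],
                                    HPT_SITE, "H",
                                    comparison_positions=list(HPT_OTHER_H)),
        "RRB": PhosphoSiteReference("RRB", proteins["ARR1_SYN"],
                                    RRB_SITE, "D",
                                    comparison_positions=list(RRB_OTHER_D)),
        "RRA": PhosphoSiteReference("RRA", proteins["ARR6_SYN"],
                                    RRB_SITE, "D"),
        "HK": PhosphoSiteReference("HK", proteins["AHK4_SYN"],
                                   HK_REC_D, "D"),
    }

    domain_spans = {
        "AHK4_SYN": {"CHASE": (1, 100), "His": (121, 185),
                     "HATPase_c": (191, 300), "Rec": (321, 410)},
        "MtHPT3_SYN": {"Hpt": (5, 140)},
        "MtRRB3_SYN": {"Rec": (1, 120), "Myb": (121, 180),
                       "C-ter": (181, 250)},
    }

    return ReferenceSet(
        proteins=proteins,
        phosphosites=phosphosites,
        identification=identification,
        hk_motifs=hk_motifs,
        hk_exemplars=("AHK2_SYN", "AHK3_SYN", "AHK4_SYN", "AHK1_SYN",
                      "CKI1_SYN", "CKI2_SYN"),
        etr_exemplars=("ETR1_SYN",),
        receiver_exemplars=("ARR6_SYN", "ARR22_SYN", "ARR1_SYN"),
        domain_spans=domain_spans,
    )


_CACHE: ReferenceSet | None = None


def default_references() -> ReferenceSet:
    """The cached package-wide reference set."""
    global _CACHE
    if _CACHE is None:
        _CACHE = build_reference_set()
    return _CACHE
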
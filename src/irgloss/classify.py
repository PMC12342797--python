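"""Domain-architecture classification of plant immune receptor genes (IRGs).

Plant immune receptors fall into two broad groups: intracellular
nucleotide-binding leucine-rich repeat receptors (NLRs) and cell-surface
pattern recognition receptors (PRRs).  Both are recognisable from the
ordered list of protein domains a domain-annotation tool (e.g. an
InterProScan-style pipeline) reports for each protein.  This module maps
each protein's ordered domain calls to one of 14 IRG classes — nine NLR
classes (CNL, CN, NL, N, TNL, TN, CTNL, TIR-X, RPW8-X) and five PRR
classes (LRR-RLK, LRR-RLP, LYK, LYP, LECRK) — or to NONE when no rule
fires.

Classification is a deterministic, most-specific-first precedence ladder:

1.  RPW8_X  — any RPW8 domain present.
2.  CTNL    — CC and TIR both occur before the first NBS, plus NBS and LRR.
3.  TNL     — TIR + NBS + LRR.
4.  CNL     — CC + NBS + LRR.
5.  TN      — TIR + NBS.
6.  CN      — CC + NBS.
7.  NL      — NBS + LRR.
8.  N       — NBS present (no other NLR-diagnostic domain).
9.  TIR_X   — TIR plus at least one other domain, with no NBS anywhere.
10. LYK     — LysM + TM + kinase.
11. LYP     — LysM + TM.
12. LECRK   — lectin + TM + kinase.
13. LRR_RLK — LRR + TM + kinase (NBS absent by this point).
14. LRR_RLP — LRR + TM, no kinase.
15. NONE    — fall-through.

NBS presence always routes a protein into the NLR branch, so the PRR
rules can never capture an NLR.  Only the CTNL "upstream" constraint is
order-sensitive; every other rule is a set-membership test.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "DOMAIN_VOCABULARY",
    "IRGClass",
    "IRG_CLASSES",
    "NLR_CLASSES",
    "PRR_CLASSES",
    "DomainArchitecture",
    "RepertoireCounts",
    "classify_protein",
    "classify_proteome",
]

#: Closed vocabulary of domain tokens. Unknown tokens are coerced to OTHER
#: on ingest (with a warning) so that open-ended "TIR-X"-style rules still
#: see them as "some additional domain".
DOMAIN_VOCABULARY = frozenset(
    {"CC", "NBS", "LRR", "TIR", "RPW8", "LYSM", "KINASE", "LECTIN", "TM", "OTHER"}
)


class IRGClass(str, Enum):
    """The 14 immune receptor gene classes, plus NONE for non-IRGs."""

    CNL = "CNL"
    CN = "CN"
    NL = "NL"
    N = "N"
    TNL = "TNL"
    TN = "TN"
    CTNL = "CTNL"
    TIR_X = "TIR_X"
    RPW8_X = "RPW8_X"
    LRR_RLK = "LRR_RLK"
    LRR_RLP = "LRR_RLP"
    LYK = "LYK"
    LYP = "LYP"
    LECRK = "LECRK"
    NONE = "NONE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Intracellular NLR classes (9).
NLR_CLASSES: tuple[IRGClass, ...] = (
    IRGClass.CNL,
    IRGClass.CN,
    IRGClass.NL,
    IRGClass.N,
    IRGClass.TNL,
    IRGClass.TN,
    IRGClass.CTNL,
    IRGClass.TIR_X,
    IRGClass.RPW8_X,
)

#: Cell-surface PRR classes (5).
PRR_CLASSES: tuple[IRGClass, ...] = (
    IRGClass.LRR_RLK,
    IRGClass.LRR_RLP,
    IRGClass.LYK,
    IRGClass.LYP,
    IRGClass.LECRK,
)

#: All 14 IRG classes in canonical order (NLRs then PRRs); NONE excluded.
IRG_CLASSES: tuple[IRGClass, ...] = NLR_CLASSES + PRR_CLASSES


@dataclass(frozen=True)
class DomainArchitecture:
    """One protein's ordered domain calls.

    Parameters
    ----------
    protein_id : str
        Unique protein identifier.
    domains : sequence of str
        Ordered domain tokens (N-terminus first). Tokens outside
        :data:`DOMAIN_VOCABULARY` are replaced by ``"OTHER"`` with a warning.
    source : str
        Free-text provenance of the annotation (tool name etc.).
    """

    protein_id: str
    domains: tuple[str, ...]
    source: str = ""

    def __init__(self, protein_id: str, domains: Sequence[str], source: str = ""):
        cleaned = []
        unknown = []
        for tok in domains:
            tok = str(tok).strip().upper()
            if tok not in DOMAIN_VOCABULARY:
                unknown.append(tok)
                tok = "OTHER"
            cleaned.append(tok)
        if not cleaned:
            raise ValueError(f"protein {protein_id!r}: domain list must be non-empty")
        if unknown:
            warnings.warn(
                f"protein {protein_id!r}: unknown domain tokens {sorted(set(unknown))} "
                "mapped to OTHER",
                stacklevel=2,
            )
        object.__setattr__(self, "protein_id", str(protein_id))
        object.__setattr__(self, "domains", tuple(cleaned))
        object.__setattr__(self, "source", source)


def classify_protein(arch: DomainArchitecture) -> IRGClass:
    """Assign a single IRG class to one domain architecture.

    The precedence ladder is documented in the module docstring. The
    function is total: every architecture maps to exactly one class, with
    :attr:`IRGClass.NONE` as the fall-through.
    """
    doms = arch.domains
    present = set(doms)

    if "RPW8" in present:
        return IRGClass.RPW8_X

    has_nbs = "NBS" in present
    if has_nbs:
        has_tir = "TIR" in present
        has_cc = "CC" in present
        has_lrr = "LRR" in present
        if has_tir and has_cc and has_lrr:
            first_nbs = doms.index("NBS")
            if doms.index("TIR") < first_nbs and doms.index("CC") < first_nbs:
                return IRGClass.CTNL
        if has_tir and has_lrr:
            return IRGClass.TNL
        if has_cc and has_lrr:
            return IRGClass.CNL
        if has_tir:
            return IRGClass.TN
        if has_cc:
            return IRGClass.CN
        if has_lrr:
            return IRGClass.NL
        return IRGClass.N

    # No NBS from here on.
    if "TIR" in present and len(present - {"TIR"}) >= 1:
        return IRGClass.TIR_X

    has_tm = "TM" in present
    has_kin = "KINASE" in present
    if "LYSM" in present and has_tm:
        return IRGClass.LYK if has_kin else IRGClass.LYP
    if "LECTIN" in present and has_tm and has_kin:
        return IRGClass.LECRK
    if "LRR" in present and has_tm:
        return IRGClass.LRR_RLK if has_kin else IRGClass.LRR_RLP
    return IRGClass.NONE


@dataclass
class RepertoireCounts:
    """Per-species counts over the 14 IRG classes.

    ``counts`` always carries all 14 classes as keys; NONE is excluded (it
    is not part of the repertoire).
    """

    species_id: str
    counts: dict[IRGClass, int] = field(
        default_factory=lambda: {c: 0 for c in IRG_CLASSES}
    )

    def __post_init__(self) -> None:
        full = {c: 0 for c in IRG_CLASSES}
        for k, v in self.counts.items():
            k = IRGClass(k)
            if k is IRGClass.NONE:
                raise ValueError("NONE is not a repertoire class")
            if v < 0:
                raise ValueError(f"negative count for {k}")
            full[k] = int(v)
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, cls: IRGClass) -> int:
        return self.counts[IRGClass(cls)]


def classify_proteome(
    archs: Iterable[DomainArchitecture], species_id: str
) -> RepertoireCounts:
    """Classify every protein of a species and tally IRG class counts.

    Proteins classified NONE are not counted (the repertoire covers IRGs
    only), so ``sum(counts) + #NONE == #proteins``.

    Raises
    ------
    ValueError
        If two architectures share a ``protein_id``.
    """
    counts = {c: 0 for c in IRG_CLASSES}
    seen: set[str] = set()
    for arch in archs:
        if arch.protein_id in seen:
            raise ValueError(f"duplicate protein_id {arch.protein_id!r}")
        seen.add(arch.protein_id)
        cls = classify_protein(arch)
        if cls is not IRGClass.NONE:
            counts[cls] += 1
    return RepertoireCounts(species_id=species_id, counts=counts)
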
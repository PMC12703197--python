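"""Mutually exclusive variant scanning and classification.

A site is *mutually exclusive* between a target group A and a background
group B when the sets of states observed in the two groups are disjoint.
Such sites are classified into four types by whether each group's state
set is a singleton:

====  ==========  ==========  ==========
Type  |set A|     |set B|     label
====  ==========  ==========  ==========
1     1           1           convergent
2     1           >1          convergent
3     >1          1           divergent
4     >1          >1          divergent
====  ==========  ==========  ==========

Types 1–2 (identical substitution across the whole polyphyletic target
group) are convergent; 3–4 are divergent. The scan runs at amino-acid,
codon, or nucleotide resolution; codon-level variants are further
classified by synonymy and by nucleotide source — a single mutually
exclusive codon position (SNV) versus complex non-exclusive nucleotide
variants (CNENV) where exclusivity only emerges at the whole-codon level.

To keep the focus on point mutations, maximal runs of adjacent variant
sites (length >= ``run_threshold``, default 2) are removed from the
report and tallied as continuous/structural.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Literal, Optional

from .seqio import (
    FormatError,
    IdentityError,
    Level,
    MultipleAlignment,
    NT_RESIDUES,
    translate_codon,
)


class AmbiguityError(ValueError):
    """Operation requires fully resolved states."""


class ScanLevel(str, Enum):
    AMINO_ACID = "amino_acid"
    CODON = "codon"
    NUCLEOTIDE = "nucleotide"


CONVERGENT = "convergent"
DIVERGENT = "divergent"

CON_SNV = "ConSNV"
DIV_SNV = "DivSNV"
CNENV = "CNENV"


@dataclass(frozen=True)
class SpeciesPartition:
    """Target group A vs background group B, with optional excluded taxa."""

    group_a: frozenset[str]
    group_b: frozenset[str]
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_a", frozenset(self.group_a))
        object.__setattr__(self, "group_b", frozenset(self.group_b))
        object.__setattr__(self, "excluded", frozenset(self.excluded))
        if not self.group_a or not self.group_b:
            raise ValueError("both species groups must be non-empty")
        if (
            self.group_a & self.group_b
            or self.group_a & self.excluded
            or self.group_b & self.excluded
        ):
            raise ValueError("group_a, group_b, and excluded must be disjoint")

    @classmethod
    def against_rest(
        cls,
        all_species: Iterable[str],
        group_a: Iterable[str],
        excluded: Iterable[str] = (),
    ) -> "SpeciesPartition":
        """Group B = every species not in A and not excluded."""
        a, ex = frozenset(group_a), frozenset(excluded)
        b = frozenset(all_species) - a - ex
        return cls(a, b, ex)


@dataclass(frozen=True)
class SiteProfilePair:
    """Distinct states observed in each group at one site."""

    set_a: frozenset[str]
    set_b: frozenset[str]
    level: ScanLevel
    scannable: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "set_a", frozenset(self.set_a))
        object.__setattr__(self, "set_b", frozenset(self.set_b))


@dataclass
class SourceTrace:
    source: str                 # ConSNV | DivSNV | CNENV
    position: Optional[int]     # 1-based codon position for SNVs, else None


@dataclass
class SiteVariant:
    gene_id: str
    site_index: int             # 1-based, in the scan level's units
    level: ScanLevel
    variant_type: int           # 1..4
    con_div: str                # convergent | divergent
    profile: SiteProfilePair
    synonymy: str = "n/a"       # synonymous | nonsynonymous | n/a
    nt_source: str = "n/a"      # ConSNV | DivSNV | CNENV | n/a
    snv_position: Optional[int] = None
    path_class: str = "unresolved"


@dataclass
class ScanReport:
    gene_id: str
    level: ScanLevel
    variants: list[SiteVariant]
    total_sites: int
    skipped_ambiguous: int
    continuous_sites: int       # variant sites removed by the run filter

    def count(self, **selectors: object) -> int:
        """Tally variants matching attribute selectors, e.g. count(con_div='convergent')."""
        out = 0
        for v in self.variants:
            if all(getattr(v, k) == val for k, val in selectors.items()):
                out += 1
        return out

    @property
    def n_convergent(self) -> int:
        return self.count(con_div=CONVERGENT)

    @property
    def n_divergent(self) -> int:
        return self.count(con_div=DIVERGENT)


# ---------------------------------------------------------------------------
# Site-level primitives
# ---------------------------------------------------------------------------

_AA_AMBIGUOUS = {"X"}
_NT_AMBIGUOUS = {"N"}


def _state_at(aln: MultipleAlignment, species: str, site: int, level: ScanLevel) -> str:
    if level is ScanLevel.CODON:
        return aln.codon(species, site)
    row = aln.row(species)
    if not 1 <= site <= aln.length:
        raise IndexError(f"site {site} outside 1..{aln.length}")
    return row[site - 1]


def _is_ambiguous(state: str, level: ScanLevel) -> bool:
    if level is ScanLevel.AMINO_ACID:
        return state in _AA_AMBIGUOUS
    if level is ScanLevel.NUCLEOTIDE:
        return state in _NT_AMBIGUOUS
    # Codon: the two clean states are a full gap and an ACGT triplet.
    # Anything else (N-containing, partial gap) hides a state that could
    # break exclusivity, so the site is unscannable.
    return state != "---" and not set(state) <= set(NT_RESIDUES)


def site_profiles(
    aln: MultipleAlignment,
    part: SpeciesPartition,
    site: int,
    level: ScanLevel | str | None = None,
) -> SiteProfilePair:
    """Distinct group-A and group-B states at a 1-based site.

    ``level`` defaults to the alignment's own level; pass
    ``ScanLevel.CODON`` on a nucleotide alignment to read whole codons
    (``site`` is then a 1-based codon index). Excluded taxa never
    contribute. Any ambiguous state in either group marks the site
    unscannable; ``-`` is an ordinary state.
    """
    if level is None:
        level = (
            ScanLevel.AMINO_ACID
            if aln.level is Level.AMINO_ACID
            else ScanLevel.NUCLEOTIDE
        )
    level = ScanLevel(level)
    if level is ScanLevel.AMINO_ACID and aln.level is not Level.AMINO_ACID:
        raise FormatError("amino-acid scan requires an amino-acid alignment")
    if level is not ScanLevel.AMINO_ACID and aln.level is not Level.NUCLEOTIDE:
        raise FormatError(f"{level.value} scan requires a nucleotide alignment")

    missing = (part.group_a | part.group_b) - set(aln.species_ids)
    if missing:
        raise IdentityError(f"group members absent from alignment: {sorted(missing)}")

    set_a = frozenset(_state_at(aln, sp, site, level) for sp in part.group_a)
    set_b = frozenset(_state_at(aln, sp, site, level) for sp in part.group_b)
    scannable = not any(_is_ambiguous(s, level) for s in set_a | set_b)
    return SiteProfilePair(set_a, set_b, level, scannable)


def classify_site_type(profile: SiteProfilePair) -> Optional[int]:
    """Type 1–4 for a mutually exclusive profile pair, else ``None``."""
    if not profile.set_a or not profile.set_b:
        raise ValueError("profile sets must be non-empty")
    if profile.set_a & profile.set_b:
        return None
    a1 = len(profile.set_a) == 1
    b1 = len(profile.set_b) == 1
    return {(True, True): 1, (True, False): 2, (False, True): 3, (False, False): 4}[
        (a1, b1)
    ]


def label_con_div(variant_type: int) -> str:
    """Types 1–2 are convergent (identical target substitution), 3–4 divergent."""
    if variant_type in (1, 2):
        return CONVERGENT
    if variant_type in (3, 4):
        return DIVERGENT
    raise ValueError(f"invalid variant type {variant_type!r}")


def classify_synonymy(codon_profile: SiteProfilePair) -> str:
    """Synonymy of a mutually exclusive codon profile.

    Nonsynonymous iff the translated amino-acid profile pair is itself
    mutually exclusive (disjoint translations); a full-gap codon
    translates to the gap state ``-`` and participates as such.
    """
    if codon_profile.level is not ScanLevel.CODON:
        raise ValueError("synonymy is defined for codon-level profiles only")
    aa_a = {translate_codon(c) for c in codon_profile.set_a}
    aa_b = {translate_codon(c) for c in codon_profile.set_b}
    if "X" in aa_a | aa_b:
        raise AmbiguityError("untranslatable codon in profile")
    return "nonsynonymous" if not (aa_a & aa_b) else "synonymous"


def trace_nucleotide_source(codon_profile: SiteProfilePair) -> SourceTrace:
    """SNV vs CNENV origin of a mutually exclusive codon profile.

    Each codon position is profiled separately; if at least one position
    is itself mutually exclusive the variant stems from single nucleotide
    variants (ConSNV when group A has exactly one state at the first such
    position, DivSNV otherwise). If no single position is exclusive the
    codon-level exclusivity is an emergent combination — CNENV.
    """
    if codon_profile.level is not ScanLevel.CODON:
        raise ValueError("nucleotide source is defined for codon-level profiles only")
    for pos in range(3):
        a_p = {c[pos] for c in codon_profile.set_a}
        b_p = {c[pos] for c in codon_profile.set_b}
        if not a_p & b_p:
            return SourceTrace(CON_SNV if len(a_p) == 1 else DIV_SNV, pos + 1)
    return SourceTrace(CNENV, None)


# ---------------------------------------------------------------------------
# Whole-alignment scan
# ---------------------------------------------------------------------------

def _n_sites(aln: MultipleAlignment, level: ScanLevel) -> int:
    return aln.n_codons if level is ScanLevel.CODON else aln.length


def scan_alignment(
    aln: MultipleAlignment,
    part: SpeciesPartition,
    level: ScanLevel | str | None = None,
    run_threshold: Optional[int] = 2,
    gene_id: str = "",
) -> ScanReport:
    """Scan every site for mutually exclusive variants and classify them.

    ``run_threshold``: maximal runs of at least this many adjacent
    variant sites (adjacency measured in this level's site units) are
    dropped from the variant list and tallied as continuous/structural;
    ``None`` disables the filter.
    """
    if level is None:
        level = (
            ScanLevel.AMINO_ACID
            if aln.level is Level.AMINO_ACID
            else ScanLevel.NUCLEOTIDE
        )
    level = ScanLevel(level)
    n = _n_sites(aln, level)
    if n == 0:
        raise FormatError("empty alignment")

    variants: list[SiteVariant] = []
    skipped = 0
    for site in range(1, n + 1):
        profile = site_profiles(aln, part, site, level)
        if not profile.scannable:
            skipped += 1
            continue
        vtype = classify_site_type(profile)
        if vtype is None:
            continue
        var = SiteVariant(
            gene_id=gene_id,
            site_index=site,
            level=level,
            variant_type=vtype,
            con_div=label_con_div(vtype),
            profile=profile,
        )
        if level is ScanLevel.CODON:
            var.synonymy = classify_synonymy(profile)
            trace = trace_nucleotide_source(profile)
            var.nt_source = trace.source
            var.snv_position = trace.position
        variants.append(var)

    continuous = 0
    if run_threshold is not None and run_threshold >= 1:
        kept: list[SiteVariant] = []
        run: list[SiteVariant] = []
        for var in variants + [None]:  # type: ignore[list-item]
            if run and (var is None or var.site_index != run[-1].site_index + 1):
                if len(run) >= run_threshold:
                    continuous += len(run)
                else:
                    kept.extend(run)
                run = []
            if var is not None:
                run.append(var)
        variants = kept

    return ScanReport(
        gene_id=gene_id,
        level=level,
        variants=variants,
        total_sites=n,
        skipped_ambiguous=skipped,
        continuous_sites=continuous,
    )
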
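"""Tree-consistent synthetic alignments with planted exclusive variants.

Background sites evolve down the tree from a random root sequence under
an equal-rates (Jukes–Cantor-style) substitution process over the
level's alphabet, so per-branch change probabilities match the
reconstruction model's transition matrix. Planted sites are overwritten
after simulation: target-group species receive the requested group-A
states and every other (non-excluded) species a group-B state, with all
requested states guaranteed to appear, realizing the requested type
exactly. The truth table records, per plant, the expected type,
convergent/divergent label, and — for codon plants — synonymy and
nucleotide source, so scanner output can be compared against a known
answer.

The generator refuses plants that cannot realize their type (e.g. a
Type 1 plant with two group-A states) and, unless explicitly allowed,
plants on adjacent sites (which the continuous-run filter would remove).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from .core_scan import (
    ScanLevel,
    SiteProfilePair,
    SpeciesPartition,
    classify_site_type,
    classify_synonymy,
    label_con_div,
    trace_nucleotide_source,
)
from .seqio import AA_RESIDUES, Level, MultipleAlignment, NT_RESIDUES


class ConfigError(ValueError):
    """A plant cannot realize its requested type."""


@dataclass
class PlantSpec:
    """One planted mutually exclusive site.

    ``site`` is 1-based in the plant level's units (codon index for
    codon-level plants on a nucleotide alignment).
    """

    site: int
    level: ScanLevel
    variant_type: int
    states_a: tuple[str, ...]
    states_b: tuple[str, ...]

    def validate(self) -> None:
        a, b = set(self.states_a), set(self.states_b)
        if not a or not b:
            raise ConfigError("plant needs at least one state per group")
        if a & b:
            raise ConfigError(f"plant at site {self.site}: state sets overlap")
        want = {1: (True, True), 2: (True, False), 3: (False, True), 4: (False, False)}
        if self.variant_type not in want:
            raise ConfigError(f"invalid type {self.variant_type}")
        a1, b1 = want[self.variant_type]
        if (len(a) == 1) != a1 or (len(b) == 1) != b1:
            raise ConfigError(
                f"plant at site {self.site}: {len(a)}/{len(b)} states cannot "
                f"realize Type {self.variant_type}"
            )
        if self.level is ScanLevel.CODON:
            for c in self.states_a + self.states_b:
                if len(c) != 3 or not (set(c) <= set(NT_RESIDUES) or c == "---"):
                    raise ConfigError(f"invalid codon state {c!r}")


@dataclass
class SimulationConfig:
    tree: dendropy.Tree
    partition: SpeciesPartition
    n_sites: int                      # in plant-level units (codons for codon sims)
    level: ScanLevel = ScanLevel.AMINO_ACID
    rate_scale: float = 1.0
    plants: Sequence[PlantSpec] = ()
    indel_prob: float = 0.0
    seed: int = 0
    allow_adjacent: bool = False
    #: redraw unplanted columns that come out mutually exclusive by chance,
    #: making the truth table exact by construction (fixture-suite mode)
    clean_background: bool = False

    def validate(self) -> None:
        sites = [p.site for p in self.plants]
        if len(set(sites)) != len(sites):
            raise ConfigError("planted sites must be distinct")
        for p in self.plants:
            if not 1 <= p.site <= self.n_sites:
                raise ConfigError(f"plant site {p.site} outside 1..{self.n_sites}")
            if p.level is not self.level:
                raise ConfigError("plant level must match simulation level")
            p.validate()
            if len(self.partition.group_a) < len(set(p.states_a)):
                raise ConfigError("more group-A states than group-A species")
        if not self.allow_adjacent:
            s = sorted(sites)
            for x, y in zip(s, s[1:]):
                if y - x == 1:
                    raise ConfigError(
                        f"plants at adjacent sites {x},{y}; set allow_adjacent=True"
                    )


@dataclass
class PlantedTruthEntry:
    site: int
    level: ScanLevel
    variant_type: int
    con_div: str
    synonymy: str = "n/a"
    nt_source: str = "n/a"
    continuous: bool = False  # adjacent to another plant: run filter removes it


PlantedTruth = list[PlantedTruthEntry]


def _alphabet(level: ScanLevel) -> str:
    return AA_RESIDUES if level is ScanLevel.AMINO_ACID else NT_RESIDUES


def _evolve(
    tree: dendropy.Tree,
    n_sites: int,
    alphabet: str,
    rate_scale: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Equal-rates simulation; returns integer state arrays per leaf."""
    k = len(alphabet)
    root_seq = rng.integers(0, k, size=n_sites)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    leaves: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seq = root_seq
        else:
            t = (node.edge.length or 0.0) * rate_scale
            p_change = (k - 1) / k * (1.0 - np.exp(-k * t / (k - 1))) if k > 1 else 0.0
            parent_seq = seqs[id(node.parent_node)]
            seq = parent_seq.copy()
            hit = rng.random(n_sites) < p_change
            if hit.any():
                # substitute to a uniformly random *different* state
                shift = rng.integers(1, k, size=int(hit.sum()))
                seq[hit] = (seq[hit] + shift) % k
        seqs[id(node)] = seq
        if node.is_leaf():
            leaves[node.taxon.label] = seq
    return leaves


def _assign_states(
    members: Sequence[str], states: Sequence[str], rng: np.random.Generator
) -> dict[str, str]:
    """Assign states so that every requested state appears at least once."""
    members = list(members)
    states = list(states)
    picks = states + [states[int(i)] for i in rng.integers(0, len(states), size=len(members) - len(states))]
    rng.shuffle(members)
    return dict(zip(members, picks))


def simulate_alignment(
    config: SimulationConfig,
) -> tuple[MultipleAlignment, PlantedTruth]:
    """Simulate an alignment down the tree and overwrite planted sites."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    level = config.level
    tree_leaves = sorted(n.taxon.label for n in config.tree.leaf_node_iter())
    part = config.partition
    known = part.group_a | part.group_b | part.excluded
    if not set(tree_leaves) <= known:
        raise ConfigError("every tree leaf must be assigned to a partition group")

    if level is ScanLevel.CODON:
        sim_alphabet = NT_RESIDUES
        n_chars = 3 * config.n_sites
    else:
        sim_alphabet = _alphabet(level)
        n_chars = config.n_sites
    leaf_ints = _evolve(config.tree, n_chars, sim_alphabet, config.rate_scale, rng)
    rows = {sp: list(sim_alphabet[i] for i in arr) for sp, arr in leaf_ints.items()}

    if config.indel_prob > 0:
        plant_chars: set[int] = set()
        for p in config.plants:
            if level is ScanLevel.CODON:
                plant_chars.update(range(3 * (p.site - 1), 3 * p.site))
            else:
                plant_chars.add(p.site - 1)
        for sp in rows:
            gaps = rng.random(n_chars) < config.indel_prob
            for i in np.flatnonzero(gaps):
                if int(i) not in plant_chars:
                    rows[sp][int(i)] = "-"

    truth: PlantedTruth = []
    group_a = sorted(part.group_a & set(tree_leaves))
    group_b = sorted(part.group_b & set(tree_leaves))
    for p in config.plants:
        assign = _assign_states(group_a, p.states_a, rng)
        assign.update(_assign_states(group_b, p.states_b, rng))
        for sp, state in assign.items():
            if level is ScanLevel.CODON:
                rows[sp][3 * (p.site - 1): 3 * p.site] = list(state)
            else:
                rows[sp][p.site - 1] = state
        entry = PlantedTruthEntry(
            site=p.site,
            level=level,
            variant_type=p.variant_type,
            con_div=label_con_div(p.variant_type),
        )
        if level is ScanLevel.CODON:
            profile = SiteProfilePair(
                frozenset(p.states_a), frozenset(p.states_b), ScanLevel.CODON
            )
            entry.synonymy = classify_synonymy(profile)
            entry.nt_source = trace_nucleotide_source(profile).source
        truth.append(entry)

    planted_sites = {p.site for p in config.plants}
    for e in truth:
        e.continuous = (e.site - 1 in planted_sites) or (e.site + 1 in planted_sites)

    if config.clean_background:
        _scrub_background(config, rows, planted_sites, rng)

    aln_level = Level.AMINO_ACID if level is ScanLevel.AMINO_ACID else Level.NUCLEOTIDE
    order = tree_leaves
    aln = MultipleAlignment(order, ["".join(rows[sp]) for sp in order], aln_level)
    return aln, sorted(truth, key=lambda e: e.site)


def _scrub_background(
    config: SimulationConfig,
    rows: dict[str, list[str]],
    planted_sites: set[int],
    rng: np.random.Generator,
) -> None:
    """Redraw unplanted columns that are mutually exclusive by chance."""
    level = config.level
    part = config.partition
    width = 3 if level is ScanLevel.CODON else 1
    sim_alphabet = NT_RESIDUES if level is ScanLevel.CODON else _alphabet(level)
    group_a = sorted(part.group_a & set(rows))
    group_b = sorted(part.group_b & set(rows))

    def exclusive(site: int) -> bool:
        lo, hi = width * (site - 1), width * site
        sa = {"".join(rows[sp][lo:hi]) for sp in group_a}
        sb = {"".join(rows[sp][lo:hi]) for sp in group_b}
        return not (sa & sb)

    for site in range(1, config.n_sites + 1):
        if site in planted_sites:
            continue
        tries = 0
        while exclusive(site) and tries < 100:
            col = _evolve(
                config.tree, width, sim_alphabet, config.rate_scale, rng
            )
            for sp in rows:
                rows[sp][width * (site - 1): width * site] = [
                    sim_alphabet[i] for i in col[sp]
                ]
            tries += 1
        if tries == 100:  # pragma: no cover - astronomically unlikely
            rows[group_b[0]][width * (site - 1): width * site] = rows[group_a[0]][
                width * (site - 1): width * site
            ]


# ---------------------------------------------------------------------------
# Standard fixture suite
# ---------------------------------------------------------------------------

#: 8-leaf tree with three separated target lineages (a1+a2, a3, a4) —
#: mirrors a polyphyletic trait group against a background.
TOY_TREE_8 = (
    "(((a1:0.1,a2:0.1):0.2,(b1:0.1,b2:0.1):0.2):0.1,"
    "((a3:0.15,b3:0.15):0.15,(a4:0.15,b4:0.15):0.15):0.1):0.0;"
)


def toy_partition_8() -> SpeciesPartition:
    return SpeciesPartition(
        frozenset({"a1", "a2", "a3", "a4"}), frozenset({"b1", "b2", "b3", "b4"})
    )


def toy_tree_8() -> dendropy.Tree:
    tree = dendropy.Tree.get(data=TOY_TREE_8, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def default_aa_plants() -> list[PlantSpec]:
    """One plant of each type, plus an adjacent pair for the run filter."""
    return [
        PlantSpec(5, ScanLevel.AMINO_ACID, 1, ("N",), ("H",)),
        PlantSpec(10, ScanLevel.AMINO_ACID, 2, ("V",), ("I", "-")),
        PlantSpec(15, ScanLevel.AMINO_ACID, 3, ("Q", "L"), ("A",)),
        PlantSpec(20, ScanLevel.AMINO_ACID, 4, ("Q", "V"), ("A", "I")),
        # adjacent pair: should be filtered out as continuous
        PlantSpec(25, ScanLevel.AMINO_ACID, 1, ("W",), ("G",)),
        PlantSpec(26, ScanLevel.AMINO_ACID, 1, ("F",), ("P",)),
    ]


def default_codon_plants() -> list[PlantSpec]:
    """Codon plants covering ConSNV / DivSNV / CNENV and both synonymies."""
    return [
        PlantSpec(3, ScanLevel.CODON, 2, ("AAT",), ("CAT", "CAC")),   # nonsyn ConSNV
        PlantSpec(6, ScanLevel.CODON, 4, ("ATT", "GTT"), ("CTT", "CTG")),  # nonsyn DivSNV
        PlantSpec(9, ScanLevel.CODON, 4, ("TCA", "AGT"), ("ACT", "ACA")),  # nonsyn CNENV
        PlantSpec(12, ScanLevel.CODON, 1, ("CTT",), ("CTC",)),        # syn ConSNV
        PlantSpec(15, ScanLevel.CODON, 4, ("CTT", "CTC"), ("CTA", "CTG")),  # syn DivSNV
    ]


_MAF_FIXTURE = """\
##maf version=1
a score=0.0
s ref.chr1 100 6 + 1000 AAT--GCA
s sp1.chr5 200 8 + 2000 AATTAGCA
s sp2.chr2 300 6 - 1500 AAC--GCA

a score=0.0
s ref.chr1 106 4 + 1000 TTGA
s sp1.chr5 208 4 + 2000 TCGA
"""


def generate_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the standard test-fixture suite; fully determined by ``seed``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tree = toy_tree_8()
    paths["tree"] = out / "tree_8leaf.nwk"
    paths["tree"].write_text(TOY_TREE_8 + "\n")

    part = toy_partition_8()
    aa_cfg = SimulationConfig(
        tree=tree, partition=part, n_sites=40, level=ScanLevel.AMINO_ACID,
        plants=default_aa_plants(), seed=seed, allow_adjacent=True,
        clean_background=True,
    )
    aa_aln, aa_truth = simulate_alignment(aa_cfg)
    paths["aa_alignment"] = out / "aa_alignment.faa"
    _write_fasta(aa_aln, paths["aa_alignment"])
    paths["aa_truth"] = out / "aa_truth.tsv"
    _write_truth(aa_truth, paths["aa_truth"])

    codon_cfg = SimulationConfig(
        tree=tree, partition=part, n_sites=20, level=ScanLevel.CODON,
        plants=default_codon_plants(), seed=seed + 1, clean_background=True,
    )
    codon_aln, codon_truth = simulate_alignment(codon_cfg)
    paths["codon_alignment"] = out / "codon_alignment.fna"
    _write_fasta(codon_aln, paths["codon_alignment"])
    paths["codon_truth"] = out / "codon_truth.tsv"
    _write_truth(codon_truth, paths["codon_truth"])

    paths["maf"] = out / "blocks.maf"
    paths["maf"].write_text(_MAF_FIXTURE)

    manifest = {name: p.name for name, p in paths.items()}
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths


def _write_fasta(aln: MultipleAlignment, path: Path) -> None:
    from .seqio import write_fasta_alignment

    write_fasta_alignment(aln, path)


def _write_truth(truth: PlantedTruth, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tlevel\tvariant_type\tcon_div\tsynonymy\tnt_source\tcontinuous\n")
        for e in truth:
            fh.write(
                f"{e.site}\t{e.level.value}\t{e.variant_type}\t{e.con_div}\t"
                f"{e.synonymy}\t{e.nt_source}\t{int(e.continuous)}\n"
            )
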
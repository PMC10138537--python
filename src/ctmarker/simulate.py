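"""Ground-truthed synthetic datasets for the marker analysis pipeline.

The generator emulates the genetic structure the analysis assumes for a
single-copy cT-DNA marker in a polyploid plant genus:

* a Yule (pure-birth) species tree;
* a protein-coding marker evolved along the tree under a GTR substitution
  process, with frame-preserving indels (lengths always multiples of three)
  inherited by descendant lineages;
* per-species allele pools built by adding private substitutions to the
  species haplotype (a star-shaped, infinite-sites-style model: each private
  mutation hits a column not mutated before within that species);
* diploid/tetraploid/hexaploid genotypes drawn from the pool, with a
  selfing probability that raises homozygosity;
* occasional large-deletion alleles mimicking the mutated marker copies
  seen in swamp cranberry;
* Sanger-style rendering of each genotype: agreeing columns give the base,
  substitution heterozygosity gives the IUPAC code, and a heterozygous
  indel makes the trace unreadable downstream of the conflict (such samples
  would need cloning in the wet lab).

Indels are tracked in root coordinates, so the ground-truth alleles of the
whole dataset stay co-aligned; all downstream stages can therefore be
checked against the truth by direct column scans.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .seq_io import Alignment, NucSequence, SampleRecord, iupac_code
from .phylo.gtr import BASES, GTRParams, transition_matrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "IndelEvent",
    "simulate_yule_tree",
    "evolve_marker",
    "sample_population",
    "render_sanger_consensus",
    "make_dataset",
    "write_dataset",
    "simulate_species_panel",
    "synthetic_reference_fragment",
]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults for the synthetic generator.

    ``subst_rate`` is the expected root-to-tip divergence in substitutions
    per site (the species tree is rescaled to this height), chosen so that
    interspecific distances sit at a few percent, well above the
    within-species diversity produced by ``within_species_theta`` expected
    private substitutions per allele — the regime the marker shows in real
    data. ``indel_length_units`` are drawn geometrically and multiplied by
    three, so every indel is frame-preserving.
    """

    n_species: int = 8
    birth_rate: float = 1.0
    marker_length: int = 876
    subst_rate: float = 0.02
    within_species_theta: float = 1.5
    min_private_mutations: int = 1
    indel_rate: float = 0.3
    indel_length_geom_p: float = 0.5
    alleles_per_species: int = 4
    samples_per_species: int = 8
    ploidies: dict[str, int] | None = None
    selfing: float = 0.3
    deletion_allele_frequency: float = 0.1
    deletion_span: tuple[int, int] = (198, 800)
    gtr: GTRParams = field(default_factory=GTRParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.marker_length % 3:
            raise ValueError("marker_length must be divisible by 3")
        for name in ("birth_rate", "subst_rate", "within_species_theta", "indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("selfing", "deletion_allele_frequency"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.deletion_span
        if not (1 <= lo <= hi <= self.marker_length) or (hi - lo + 1) % 3:
            raise ValueError("deletion_span must lie in the CDS with length % 3 == 0")


@dataclass(frozen=True)
class IndelEvent:
    """A simulated indel: where in the tree it happened and its size."""

    lineage: str  # leaf label or internal branch id
    kind: str  # 'insertion' | 'deletion'
    length: int  # nucleotides


@dataclass
class GroundTruth:
    """Everything the generator knows, for use as a recovery-test oracle."""

    species_tree: dendropy.Tree
    root_sequence: str  # ungapped ancestral marker
    column_order: list[int]  # master column ids, alignment order
    root_columns: dict[int, int]  # col id -> 1-based root coordinate
    allele_alignment: dict[str, list[str]]  # species -> aligned allele seqs
    genotypes: dict[str, tuple[int, ...]]  # sample -> allele indices
    sample_species: dict[str, str]
    indel_events: list[IndelEvent]

    def alleles_of(self, sample_id: str) -> list[str]:
        sp = self.sample_species[sample_id]
        return [self.allele_alignment[sp][i] for i in self.genotypes[sample_id]]

    def genotype_multiset(self, sample_id: str) -> tuple[int, ...]:
        return tuple(sorted(self.genotypes[sample_id]))


# ---------------------------------------------------------------------------
# species tree


def simulate_yule_tree(
    n_species: int, birth_rate: float = 1.0, seed: int | np.random.Generator = 0
) -> dendropy.Tree:
    """Pure-birth ultrametric tree with *n_species* leaves (sp1..spN).

    Inter-event waiting times with k lineages are Exp(k * birth_rate); the
    expected root height is sum_{k=2..n} 1/(k * birth_rate). Deterministic
    under a fixed seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    root = dendropy.Node()
    first = [dendropy.Node(), dendropy.Node()]
    for child in first:
        root.add_child(child)
    start = {id(c): 0.0 for c in first}
    active = list(first)
    t = 0.0
    while True:
        t += rng.exponential(1.0 / (len(active) * birth_rate))
        if len(active) == n_species:
            break
        node = active.pop(rng.integers(len(active)))
        node.edge.length = t - start[id(node)]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            start[id(child)] = t
            active.append(child)
    for node in active:
        node.edge.length = t - start[id(node)]
    tree = dendropy.Tree()
    tree.seed_node = root
    ns = tree.taxon_namespace
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = ns.new_taxon(f"sp{i}")
    return tree


# ---------------------------------------------------------------------------
# marker evolution


def _tree_height(tree: dendropy.Tree) -> float:
    leaf = next(tree.leaf_node_iter())
    h = 0.0
    node = leaf
    while node.parent_node is not None:
        h += node.edge.length or 0.0
        node = node.parent_node
    return h


class _Lineage:
    """A sequence as a mapping of present master columns to base indices."""

    __slots__ = ("cols",)

    def __init__(self, cols: dict[int, int]):
        self.cols = cols

    def copy(self) -> "_Lineage":
        return _Lineage(dict(self.cols))


def evolve_marker(
    tree: dendropy.Tree, config: SimulationConfig, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Evolve the marker along *tree* and build per-species allele pools.

    Returns a :class:`GroundTruth` whose allele sequences are co-aligned in
    master (root-anchored) coordinates; genotypes are not sampled yet.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    params = config.gtr
    pi = np.asarray(params.base_freqs)
    length = config.marker_length

    height = _tree_height(tree)
    scale = config.subst_rate / height if height > 0 else 0.0

    order: list[int] = list(range(length))
    next_col = itertools.count(length)
    root_cols = {c: c + 1 for c in range(length)}  # col id -> root coordinate

    root_seq = _Lineage(
        {c: int(b) for c, b in zip(order, rng.choice(4, size=length, p=pi))}
    )
    states: dict[int, _Lineage] = {id(tree.seed_node): root_seq}
    events: list[IndelEvent] = []

    branch_counter = itertools.count(1)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        lineage = states[id(node.parent_node)].copy()
        t = (node.edge.length or 0.0) * scale
        _apply_substitutions(lineage, params, t, rng)
        label = (
            node.taxon.label if node.is_leaf() else f"branch{next(branch_counter)}"
        )
        _apply_indels(lineage, config, order, next_col, pi, rng, events, label)
        states[id(node)] = lineage

    col_rank = {c: i for i, c in enumerate(order)}
    species_state = {
        leaf.taxon.label: states[id(leaf)] for leaf in tree.leaf_node_iter()
    }

    allele_alignment: dict[str, list[str]] = {}
    for species in sorted(species_state):
        base = species_state[species]
        pool: list[_Lineage] = []
        mutated: set[int] = set()
        for _ in range(config.alleles_per_species):
            allele = base.copy()
            k = max(config.min_private_mutations, int(rng.poisson(config.within_species_theta)))
            candidates = sorted(set(allele.cols) - mutated)
            k = min(k, len(candidates))
            if k:
                chosen = rng.choice(len(candidates), size=k, replace=False)
                for ci in chosen:
                    col = candidates[int(ci)]
                    old = allele.cols[col]
                    allele.cols[col] = int((old + 1 + rng.integers(3)) % 4)
                    mutated.add(col)
            pool.append(allele)
        # occasional large-deletion allele (applied to a full-span allele)
        if rng.random() < config.deletion_allele_frequency:
            lo, hi = config.deletion_span
            span_cols = [c for c, pos in root_cols.items() if lo <= pos <= hi]
            eligible = [
                a for a in pool if all(c in a.cols for c in span_cols)
            ]
            if eligible:
                victim = eligible[int(rng.integers(len(eligible)))]
                for c in span_cols:
                    del victim.cols[c]
                events.append(IndelEvent(species, "deletion", len(span_cols)))
        # deduplicate identical alleles
        seen: dict[tuple, int] = {}
        unique: list[_Lineage] = []
        for allele in pool:
            key = tuple(sorted(allele.cols.items()))
            if key not in seen:
                seen[key] = len(unique)
                unique.append(allele)
        allele_alignment[species] = [
            _render_aligned(a, order, col_rank) for a in unique
        ]

    root_render = _render_aligned(root_seq, order, col_rank)
    return GroundTruth(
        species_tree=tree,
        root_sequence=root_render.replace("-", ""),
        column_order=order,
        root_columns=root_cols,
        allele_alignment=allele_alignment,
        genotypes={},
        sample_species={},
        indel_events=events,
    )


def _apply_substitutions(lineage, params, t, rng) -> None:
    if t <= 0 or not lineage.cols:
        return
    p = transition_matrix(params, t)
    cum = np.cumsum(p, axis=1)
    cols = list(lineage.cols)
    u = rng.random(len(cols))
    for col, uu in zip(cols, u):
        row = cum[lineage.cols[col]]
        lineage.cols[col] = int(min(np.searchsorted(row, uu, side="right"), 3))


def _apply_indels(lineage, config, order, next_col, pi, rng, events, label) -> None:
    n_events = rng.poisson(config.indel_rate)
    for _ in range(n_events):
        units = int(rng.geometric(config.indel_length_geom_p))
        size = 3 * units
        if rng.random() < 0.5:  # deletion
            present = [c for c in order if c in lineage.cols]
            if len(present) <= size + 3:  # refuse to wipe out the lineage
                continue
            start = int(rng.integers(len(present) - size + 1))
            for c in present[start : start + size]:
                del lineage.cols[c]
            events.append(IndelEvent(label, "deletion", size))
        else:  # insertion: new master columns, absent elsewhere
            at = int(rng.integers(len(order) + 1))
            new_ids = [next(next_col) for _ in range(size)]
            order[at:at] = new_ids
            bases = rng.choice(4, size=size, p=pi)
            for cid, b in zip(new_ids, bases):
                lineage.cols[cid] = int(b)
            events.append(IndelEvent(label, "insertion", size))


def _render_aligned(lineage: _Lineage, order: list[int], col_rank=None) -> str:
    return "".join(
        BASES[lineage.cols[c]] if c in lineage.cols else "-" for c in order
    )


# ---------------------------------------------------------------------------
# genotypes and Sanger rendering


def sample_population(
    allele_pool: list,
    n_samples: int,
    ploidy: int,
    selfing: float,
    allele_freqs,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "s",
) -> list[tuple[str, tuple[int, ...]]]:
    """Draw genotypes (multisets of pool indices) from an allele pool.

    Each sample draws *ploidy* alleles from *allele_freqs*; with
    probability *selfing* a single draw is duplicated across the whole
    genotype, forcing homozygosity.
    """
    if not allele_pool:
        raise ValueError("empty allele pool")
    freqs = np.asarray(allele_freqs, float)
    if freqs.shape != (len(allele_pool),) or abs(freqs.sum() - 1) > 1e-8:
        raise ValueError("allele_freqs must sum to 1 over the pool")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(1, n_samples + 1):
        if rng.random() < selfing:
            genotype = (int(rng.choice(len(allele_pool), p=freqs)),) * ploidy
        else:
            genotype = tuple(
                int(x) for x in rng.choice(len(allele_pool), size=ploidy, p=freqs)
            )
        out.append((f"{id_prefix}{i:02d}", tuple(sorted(genotype))))
    return out


def render_sanger_consensus(allele_seqs: list[str], seq_id: str = "consensus"):
    """Collapse a genotype's aligned alleles into one Sanger-style consensus.

    Columns where all alleles agree give that base; substitution
    heterozygosity gives the IUPAC code of the base set. A column where
    some alleles have a base and others a gap is a heterozygous indel: the
    electropherogram becomes uninterpretable from there on, so every
    downstream column is rendered ``N`` and the consensus is flagged
    unreadable.

    Returns ``(NucSequence, readable)``.
    """
    if not allele_seqs:
        raise ValueError("empty allele multiset")
    lengths = {len(s) for s in allele_seqs}
    if len(lengths) != 1:
        raise ValueError("alleles must share coordinates (equal aligned length)")
    n_cols = lengths.pop()
    out = []
    readable = True
    for i in range(n_cols):
        chars = [s[i] for s in allele_seqs]
        present = [c for c in chars if c != "-"]
        if not present:
            out.append("-")
        elif len(present) < len(chars):
            readable = False
            out.extend("N" * (n_cols - i))
            break
        else:
            bases = set(present)
            out.append(next(iter(bases)) if len(bases) == 1 else iupac_code(bases))
    return NucSequence(seq_id, "".join(out)), readable


# ---------------------------------------------------------------------------
# end-to-end dataset


_PLOIDY_CYCLE = (2, 2, 4, 2, 6, 2, 2, 4)


@dataclass
class SimulatedDataset:
    """A complete synthetic study: truth, samples and unreadable list."""

    config: SimulationConfig
    truth: GroundTruth
    samples: list[SampleRecord]
    unreadable: list[str]

    def alignment(self, include_unreadable: bool = False) -> Alignment:
        bad = set() if include_unreadable else set(self.unreadable)
        return Alignment(
            [s.sequence for s in self.samples if s.sample_id not in bad]
        )


def make_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate tree, alleles, genotypes and Sanger consensus sequences."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_yule_tree(config.n_species, config.birth_rate, rng)
    truth = evolve_marker(tree, config, rng)

    species_list = sorted(truth.allele_alignment)
    ploidies = config.ploidies or {
        sp: _PLOIDY_CYCLE[i % len(_PLOIDY_CYCLE)]
        for i, sp in enumerate(species_list)
    }
    samples: list[SampleRecord] = []
    unreadable: list[str] = []
    for sp in species_list:
        pool = truth.allele_alignment[sp]
        freqs = rng.dirichlet(np.ones(len(pool)))
        genotypes = sample_population(
            pool,
            config.samples_per_species,
            ploidies.get(sp, 2),
            config.selfing,
            freqs,
            rng,
            id_prefix=f"{sp}_",
        )
        for sample_id, indices in genotypes:
            truth.genotypes[sample_id] = indices
            truth.sample_species[sample_id] = sp
            seqs = [pool[i] for i in indices]
            consensus, readable = render_sanger_consensus(seqs, sample_id)
            if not readable:
                unreadable.append(sample_id)
            samples.append(
                SampleRecord(
                    sample_id, sp, f"loc{1 + len(samples) % 5}",
                    ploidies.get(sp, 2), consensus,
                )
            )
    return SimulatedDataset(config, truth, samples, unreadable)


def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, str]:
    """Write samples.fasta / samples.tsv / truth files / tree.nwk."""
    from pathlib import Path

    from .seq_io import write_fasta, write_sample_table
    from .phylo.trees import to_newick

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["samples.fasta"] = str(out / "samples.fasta")
    write_fasta([s.sequence for s in dataset.samples], paths["samples.fasta"])
    paths["samples.tsv"] = str(out / "samples.tsv")
    write_sample_table(dataset.samples, paths["samples.tsv"])
    truth_seqs = []
    for sp, pool in sorted(dataset.truth.allele_alignment.items()):
        for i, seq in enumerate(pool):
            truth_seqs.append(NucSequence(f"{sp}_allele{i}", seq))
    paths["truth_alleles.fasta"] = str(out / "truth_alleles.fasta")
    write_fasta(truth_seqs, paths["truth_alleles.fasta"])
    paths["truth_assignments.tsv"] = str(out / "truth_assignments.tsv")
    with open(paths["truth_assignments.tsv"], "w") as fh:
        fh.write("sample_id\tspecies\tallele_indices\n")
        for sid, idx in sorted(dataset.truth.genotypes.items()):
            sp = dataset.truth.sample_species[sid]
            fh.write(f"{sid}\t{sp}\t{','.join(map(str, idx))}\n")
    paths["tree.nwk"] = str(out / "tree.nwk")
    with open(paths["tree.nwk"], "w") as fh:
        fh.write(to_newick(dataset.truth.species_tree) + "\n")
    return paths


# ---------------------------------------------------------------------------
# single-species panel (phasing recovery experiments)


@dataclass
class SpeciesPanel:
    """A one-species diploid/polyploid panel with known allele truth."""

    species: str
    alleles: list[str]  # aligned (gap-free here) allele sequences
    genotypes: dict[str, tuple[int, ...]]
    samples: list[SampleRecord]

    def alignment(self) -> Alignment:
        return Alignment([s.sequence for s in self.samples])


def simulate_species_panel(
    n_samples: int = 20,
    n_alleles: int = 5,
    marker_length: int = 876,
    theta: float = 2.0,
    ploidy: int = 2,
    selfing: float = 0.2,
    ensure_homozygote_per_allele: bool = True,
    species: str = "spX",
    seed: int | np.random.Generator = 0,
) -> SpeciesPanel:
    """A single-species panel under the star-shaped private-mutation model.

    Every allele carries at least one private substitution at a column no
    other allele of the panel mutates, which makes each heterozygote's
    ambiguity pattern explainable by exactly one allele pair. With
    *ensure_homozygote_per_allele* the first ``n_alleles`` genotypes are
    homozygotes, one per allele, so the seeding condition for parsimony
    phasing holds by construction.
    """
    rng = np.random.default_rng(seed)
    base = rng.choice(4, size=marker_length)
    available = list(range(marker_length))
    rng.shuffle(available)
    cursor = 0
    alleles = []
    for _ in range(n_alleles):
        k = max(1, int(rng.poisson(theta)))
        allele = base.copy()
        for _ in range(k):
            col = available[cursor]
            cursor += 1
            allele[col] = (allele[col] + 1 + rng.integers(3)) % 4
        alleles.append("".join(BASES[b] for b in allele))
    freqs = rng.dirichlet(np.ones(n_alleles))
    genotypes: dict[str, tuple[int, ...]] = {}
    if ensure_homozygote_per_allele:
        for i in range(n_alleles):
            genotypes[f"{species}_h{i + 1:02d}"] = (i,) * ploidy
    remaining = n_samples - len(genotypes)
    if remaining < 0:
        raise ValueError("n_samples too small to seed one homozygote per allele")
    for sid, geno in sample_population(
        alleles, remaining, ploidy, selfing, freqs, rng, id_prefix=f"{species}_r"
    ):
        genotypes[sid] = geno
    samples = []
    for sid in sorted(genotypes):
        seqs = [alleles[i] for i in genotypes[sid]]
        consensus, readable = render_sanger_consensus(seqs, sid)
        assert readable  # no indels in a panel
        samples.append(SampleRecord(sid, species, "loc1", ploidy, consensus))
    return SpeciesPanel(species, alleles, genotypes, samples)


# ---------------------------------------------------------------------------
# synthetic reference fragment (in-silico PCR / ORF playground)


@dataclass(frozen=True)
class ReferenceGeometry:
    """1-based landmark coordinates of the synthetic reference fragment."""

    fragment_length: int
    cds_start: int
    cds_end: int  # inclusive, stop codon included
    amplicons: dict[str, tuple[int, int]]  # primer pair name -> (start, end)


_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _random_codons(rng, n: int) -> str:
    out = []
    while len(out) < n:
        codon = "".join(BASES[b] for b in rng.integers(0, 4, size=3))
        if codon not in _STOP_CODONS:
            out.append(codon)
    return "".join(out)


def synthetic_reference_fragment():
    """A synthetic stand-in for the marker's genomic reference fragment.

    The real reference is a public genome contig that cannot be bundled
    here; this constructed fragment reproduces its published geometry: the
    three primer pairs of :data:`ctmarker.marker_tools.STUDY_PRIMERS` yield
    single products of their published sizes (1503, 1002 and 838 nt), and
    the fragment carries an ATG-initiated 876-nt coding sequence (292
    codons, stop excluded) fully contained in the 1002-nt product.

    Deterministic; returns ``(NucSequence, ReferenceGeometry)``.
    """
    from .marker_tools import STUDY_PRIMERS, find_amplicon, find_orf
    from .seq_io import revcomp

    total = 1600
    cds_start, coding_len = 91, 876
    cds_end = cds_start + coding_len + 3 - 1  # stop codon included
    layout = {
        # pair name -> (fwd primer 1-based start, amplicon size)
        "Vacc_vn": (31, 1503),
        "Vacc": (61, 1002),
        "Vacc_ts": (111, 838),
    }
    for attempt in range(64):
        rng = np.random.default_rng(20_230_408 + attempt)
        seq = list("".join(BASES[b] for b in rng.integers(0, 4, size=total)))

        def stamp(pos1, text):
            seq[pos1 - 1 : pos1 - 1 + len(text)] = list(text)

        # coding sequence: ATG + non-stop codons + TAA
        stamp(cds_start, "ATG" + _random_codons(rng, coding_len // 3 - 1) + "TAA")
        for name, (fstart, size) in layout.items():
            pair = STUDY_PRIMERS[name]
            stamp(fstart, pair.forward.residues)
            rc = revcomp(pair.reverse.residues)
            stamp(fstart + size - len(rc), rc)
        fragment = NucSequence("synthetic_reference", "".join(seq))

        # validate: unique products of the published sizes, intact longest ORF
        ok = True
        for name, (fstart, size) in layout.items():
            hits = find_amplicon(fragment, STUDY_PRIMERS[name])
            if len(hits) != 1 or hits[0].length != size or hits[0].start != fstart:
                ok = False
        orfs = find_orf(fragment, min_length=300)
        if not (
            ok
            and orfs
            and orfs[0].cds_start == cds_start
            and orfs[0].cds_end == cds_end
            and orfs[0].strand == "+"
        ):
            continue
        geometry = ReferenceGeometry(
            fragment_length=total,
            cds_start=cds_start,
            cds_end=cds_end,
            amplicons={
                name: (fstart, fstart + size - 1)
                for name, (fstart, size) in layout.items()
            },
        )
        return fragment, geometry
    raise RuntimeError("could not construct a valid synthetic reference fragment")


def synthetic_reference_cds() -> NucSequence:
    """The 876-nt coding sequence (stop codon excluded) of the synthetic
    reference fragment, used as the coordinate system for indel reports."""
    fragment, geo = synthetic_reference_fragment()
    return NucSequence(
        "synthetic_reference_cds",
        fragment.residues[geo.cds_start - 1 : geo.cds_end - 3],
    )
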
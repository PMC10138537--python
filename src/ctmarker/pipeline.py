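"""End-to-end marker analysis: sites -> phase -> stats -> consensus -> trees.

The pipeline consumes an aligned FASTA of per-sample marker consensus
sequences (IUPAC ambiguity codes marking heterozygous positions) plus a
sample metadata table, and produces per-species polymorphic sites, phased
alleles, zygosity and frequency summaries, variability statistics,
optional hybrid-allele exclusion, per-species consensus sequences, and
maximum-likelihood trees of the alleles and of the species consensus
sequences. Samples whose consensus is unreadable (N runs from a
heterozygous indel) are set aside and reported as needing cloning; alleles
that are not full length against the reference coding sequence are
excluded from tree building.

Every stage logs its input/output counts, and a manifest records versions,
seed and parameters, so a rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .phasing import (
    PhaseAssignment,
    clark_resolve,
    explain_polyploid,
    name_alleles,
    phase_report,
    realize_alleles,
    seed_pool,
)
from .phylo import filter_columns, ml_search, to_newick
from .polymorphism import binary_encode, deletion_span, find_polymorphic_sites
from .popstats import (
    allele_frequencies,
    flag_hybrid_alleles,
    species_consensus,
    variability_report,
)
from .seq_io import (
    Alignment,
    NucSequence,
    SampleRecord,
    parse_fasta,
    read_sample_table,
    write_fasta,
)

logger = logging.getLogger("ctmarker")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "analyze_samples"]


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    alignment_fasta: str
    metadata_tsv: str
    reference_fasta: str | None = None  # ungapped marker CDS for indel calls
    min_site_coverage: float = 0.95
    exclude_hybrids: bool = False
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        for path in (self.alignment_fasta, self.metadata_tsv, self.reference_fasta):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)
        if not 0 <= self.min_site_coverage <= 1:
            raise ValueError("min_site_coverage must be in [0, 1]")


@dataclass
class PipelineResult:
    """Everything one run computed, stage by stage."""

    sites: dict
    patterns: dict
    assignments: dict[str, list[PhaseAssignment]]
    pools: dict
    allele_names: dict[str, dict[str, str]]
    alleles: dict[str, list]  # species -> realized Allele objects
    report: pd.DataFrame
    frequencies: dict
    variability: object | None
    hybrid_flags: list
    consensus: dict
    allele_tree: object | None
    species_tree: object | None
    unreadable: list[str]
    not_full_length: list[str]
    messages: list[str] = field(default_factory=list)


def _species_ploidy(samples: list[SampleRecord]) -> dict[str, int]:
    out: dict[str, int] = {}
    for s in samples:
        out[s.species] = max(out.get(s.species, 0), s.ploidy)
    return out


def analyze_samples(
    samples: list[SampleRecord],
    reference_cds: NucSequence | None = None,
    *,
    min_site_coverage: float = 0.95,
    exclude_hybrids: bool = False,
    tree_method: str = "ml",
) -> PipelineResult:
    """Run the full analysis on in-memory samples (the library entry point).

    ``tree_method`` may be ``"ml"`` (GTR maximum likelihood from NJ/BioNJ
    starts) or ``"nj"`` (distance tree only), trading search time for
    thoroughness on large allele sets.
    """
    messages: list[str] = []

    readable = [s for s in samples if "N" not in s.sequence.residues]
    unreadable = sorted(s.sample_id for s in samples if "N" in s.sequence.residues)
    if unreadable:
        msg = f"{len(unreadable)} unreadable consensus sequences set aside (cloning needed)"
        logger.info(msg)
        messages.append(msg)
    if not readable:
        raise ValueError("no readable samples")

    alignment = Alignment([s.sequence for s in readable])
    by_species: dict[str, list[SampleRecord]] = {}
    for s in readable:
        by_species.setdefault(s.species, []).append(s)

    sites, patterns, assignments, pools = {}, {}, {}, {}
    allele_names: dict[str, dict[str, str]] = {}
    alleles: dict[str, list] = {}
    ploidies = _species_ploidy(readable)

    for sp in sorted(by_species):
        members = by_species[sp]
        sp_sites = find_polymorphic_sites(
            alignment, sp, [s.sample_id for s in members]
        )
        sites[sp] = sp_sites
        sp_patterns = [binary_encode(sp_sites, s.sequence) for s in members]
        patterns[sp] = sp_patterns
        pool = seed_pool(sp_patterns)
        diploid = [p for p, s in zip(sp_patterns, members) if s.ploidy == 2]
        poly = [(p, s) for p, s in zip(sp_patterns, members) if s.ploidy > 2]
        asg, pool = clark_resolve(diploid, pool)
        for pat, s in poly:
            asg.append(explain_polyploid(pat, pool, s.ploidy))
        assignments[sp] = asg
        pools[sp] = pool
        logger.info(
            "%s: %d samples, %d sites, %d resolved",
            sp, len(members), len(sp_sites),
            sum(a.status == "resolved" for a in asg),
        )
        names = name_alleles(asg, prefix=f"{sp}_", ploidy=ploidies[sp])
        allele_names[sp] = names
        backbone = species_consensus(
            [s.sequence for s in members], sp
        ).sequence
        alleles[sp] = realize_alleles(sp_sites, names, backbone)

    report = phase_report(assignments, ploidies)
    frequencies = {
        sp: allele_frequencies(
            assignments[sp], sp, allele_names[sp], ploidies[sp]
        )
        for sp in sorted(assignments)
    }

    alleles_by_species = {
        sp: [a.sequence for a in alleles[sp]] for sp in alleles if alleles[sp]
    }
    variability = None
    if len([sp for sp in alleles_by_species if alleles_by_species[sp]]) >= 2:
        variability = variability_report(alleles_by_species)

    hybrid_flags = []
    excluded_by_species: dict[str, list[tuple[str, str]]] = {}
    if len(alleles_by_species) >= 2:
        hybrid_flags = flag_hybrid_alleles(alleles_by_species)
        if exclude_hybrids:
            for allele_id, reason in hybrid_flags:
                sp = allele_id.rsplit("_", 1)[0]
                excluded_by_species.setdefault(sp, []).append((allele_id, reason))

    consensus = {}
    for sp, seqs in alleles_by_species.items():
        try:
            consensus[sp] = species_consensus(
                seqs, sp, excluded_by_species.get(sp, ())
            )
        except ValueError:
            messages.append(f"{sp}: all alleles excluded, no consensus")

    # full-length filter before tree building
    all_alleles = [a for sp in sorted(alleles) for a in alleles[sp]]
    excluded_ids = {aid for flags in excluded_by_species.values() for aid, _ in flags}
    not_full_length: list[str] = []
    tree_input = []
    kept = [a for a in all_alleles if a.allele_id not in excluded_ids]
    # without a reference, fall back to a length heuristic: alleles far
    # shorter than the median ungapped length carry a large deletion
    lengths = sorted(len(a.sequence.ungapped()) for a in kept)
    median_len = lengths[len(lengths) // 2] if lengths else 0
    for allele in kept:
        seq = allele.sequence
        if reference_cds is not None:
            if deletion_span(seq.ungapped(), reference_cds) is not None:
                not_full_length.append(allele.allele_id)
                continue
        elif len(seq.ungapped()) < 0.9 * median_len:
            not_full_length.append(allele.allele_id)
            continue
        tree_input.append(seq)
    if not_full_length:
        msg = f"{len(not_full_length)} alleles not full-length, excluded from trees"
        logger.info(msg)
        messages.append(msg)

    allele_tree = _build_tree(tree_input, min_site_coverage, tree_method, messages, "allele")
    species_tree = _build_tree(
        [c.sequence for _, c in sorted(consensus.items())],
        min_site_coverage, tree_method, messages, "species",
    )

    return PipelineResult(
        sites=sites,
        patterns=patterns,
        assignments=assignments,
        pools=pools,
        allele_names=allele_names,
        alleles=alleles,
        report=report,
        frequencies=frequencies,
        variability=variability,
        hybrid_flags=hybrid_flags,
        consensus=consensus,
        allele_tree=allele_tree,
        species_tree=species_tree,
        unreadable=unreadable,
        not_full_length=sorted(not_full_length),
        messages=messages,
    )


def _build_tree(seqs, min_site_coverage, method, messages, label):
    if len(seqs) < 3:
        messages.append(f"{label} tree skipped: fewer than 3 sequences")
        logger.info(messages[-1])
        return None
    aln = filter_columns(Alignment(seqs), min_site_coverage)
    logger.info("%s tree: %d sequences, %d columns retained", label, len(aln), aln.column_count)
    if method == "nj":
        from .phylo import distance_matrix, nj_tree

        return nj_tree(distance_matrix(aln, "tn93"))
    return ml_search(aln)


def run_pipeline(config: PipelineConfig, tree_method: str = "ml") -> PipelineResult:
    """File-based pipeline driver: read inputs, analyze, write outputs."""
    seqs = parse_fasta(config.alignment_fasta)
    samples = read_sample_table(
        config.metadata_tsv, {s.id: s for s in seqs}
    )
    reference = None
    if config.reference_fasta:
        reference = parse_fasta(config.reference_fasta)[0].ungapped()
    result = analyze_samples(
        samples,
        reference,
        min_site_coverage=config.min_site_coverage,
        exclude_hybrids=config.exclude_hybrids,
        tree_method=tree_method,
    )
    if config.outdir:
        write_outputs(result, config)
    return result


def write_outputs(result: PipelineResult, config: PipelineConfig) -> dict[str, str]:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    site_rows = [
        (sp, s.column, s.major, s.minor, s.major_count, s.minor_count)
        for sp in sorted(result.sites)
        for s in result.sites[sp].sites
    ]
    paths["sites"] = str(out / "sites.tsv")
    pd.DataFrame(
        site_rows,
        columns=["species", "column", "major", "minor", "major_count", "minor_count"],
    ).to_csv(paths["sites"], sep="\t", index=False)

    pattern_rows = [
        (sp, p.sample_id, p.codes)
        for sp in sorted(result.patterns)
        for p in result.patterns[sp]
    ]
    paths["patterns"] = str(out / "patterns.tsv")
    pd.DataFrame(
        pattern_rows, columns=["species", "sample_id", "pattern"]
    ).to_csv(paths["patterns"], sep="\t", index=False)

    asg_rows = []
    for sp in sorted(result.assignments):
        names = result.allele_names[sp]
        for a in result.assignments[sp]:
            asg_rows.append(
                (
                    sp,
                    a.sample_id,
                    a.status,
                    ",".join(names.get(b, b) for b in a.alleles),
                )
            )
    paths["assignments"] = str(out / "assignments.tsv")
    pd.DataFrame(
        asg_rows, columns=["species", "sample_id", "status", "alleles"]
    ).to_csv(paths["assignments"], sep="\t", index=False)

    paths["report"] = str(out / "report.tsv")
    result.report.to_csv(paths["report"], sep="\t", index=False)

    paths["frequencies"] = str(out / "frequencies.tsv")
    freq_frames = [
        result.frequencies[sp].to_frame() for sp in sorted(result.frequencies)
    ]
    pd.concat(freq_frames, ignore_index=True).to_csv(
        paths["frequencies"], sep="\t", index=False
    )

    paths["alleles"] = str(out / "alleles.fasta")
    write_fasta(
        [a.sequence for sp in sorted(result.alleles) for a in result.alleles[sp]],
        paths["alleles"],
    )
    paths["consensus"] = str(out / "consensus.fasta")
    write_fasta(
        [result.consensus[sp].sequence for sp in sorted(result.consensus)],
        paths["consensus"],
    )

    for label, tree in (
        ("allele_tree", result.allele_tree),
        ("species_tree", result.species_tree),
    ):
        if tree is not None:
            paths[label] = str(out / f"{label}.nwk")
            Path(paths[label]).write_text(to_newick(tree) + "\n")

    manifest = {
        "ctmarker_version": __version__,
        "seed": config.seed,
        "parameters": {
            "min_site_coverage": config.min_site_coverage,
            "exclude_hybrids": config.exclude_hybrids,
        },
        "inputs": {
            "alignment_fasta": str(config.alignment_fasta),
            "metadata_tsv": str(config.metadata_tsv),
            "reference_fasta": config.reference_fasta
            and str(config.reference_fasta),
        },
        "unreadable_samples": result.unreadable,
        "not_full_length": result.not_full_length,
        "messages": result.messages,
    }
    paths["manifest"] = str(out / "manifest.json")
    Path(paths["manifest"]).write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
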
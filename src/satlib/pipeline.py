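"""End-to-end orchestration: simulate/load reads -> merge -> select -> mine ->
diversity stats -> cluster -> minimum spanning tree.

One :class:`PipelineConfig` (built programmatically or parsed from a flat
INI-style file) drives all stages species by species, then pools the surviving
haplotypes into a global alignment and an abundance-weighted MST. Every stage
seed is derived from the single master seed by fixed offsets, so a config +
seed pair reproduces the whole report bundle byte for byte (timestamps are
confined to the log).
"""
from __future__ import annotations

import configparser
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import hapnet, monomers, popstats, readprep, satsim
from ._align import revcomp
from .errors import DataError, ParameterError, PipelineError, SatlibError
from .monomers import Monomer, SatConsensus
from .popstats import HaplotypeTable, HapRow

logger = logging.getLogger(__name__)

DEFAULT_SUBSAMPLE = 5_000_000

# fixed per-stage seed offsets derived from the master seed
_SEED_LIBRARY = 0
_SEED_AMPLIFY = 1_000
_SEED_ARRAY = 2_000
_SEED_READS = 3_000
_SEED_SUBSAMPLE = 4_000


@dataclass
class SimSpecies:
    """A species simulated from the shared ancestral library."""

    profile: satsim.SpeciesProfile
    n_pairs: int = 2000
    read_length: int = 250
    frag_mean: int = 400
    frag_sd: float = 25.0
    error_rate: float = 0.0


@dataclass
class FastqSpecies:
    """A species provided as paired FASTQ files."""

    species: str
    r1: str
    r2: str


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 1
    consensus_path: str | None = None
    # ancestral library (used when sim_species is non-empty)
    library_haplotypes: int = 6
    library_unit_length: int = 177
    library_divergence: float = 0.05
    sim_species: list[SimSpecies] = field(default_factory=list)
    fastq_species: list[FastqSpecies] = field(default_factory=list)
    pcr_fastas: dict[str, str] = field(default_factory=dict)
    subsample: int | None = DEFAULT_SUBSAMPLE
    # stage thresholds
    min_overlap: int = readprep.DEFAULT_MIN_OVERLAP
    max_mismatch_frac: float = readprep.DEFAULT_MAX_MISMATCH_FRAC
    min_identity: float = readprep.DEFAULT_MIN_IDENTITY
    min_aligned: int = readprep.DEFAULT_MIN_ALIGNED
    extract_identity: float = monomers.DEFAULT_EXTRACT_IDENTITY
    length_tol: float = monomers.DEFAULT_LENGTH_TOL
    cluster_threshold: float = hapnet.DEFAULT_CLUSTER_IDENTITY
    singleton_filter: bool = True
    cluster_pcr: bool = False
    indel_policy: str = "gap_as_event"

    def species_names(self) -> list[str]:
        return [s.profile.species for s in self.sim_species] + \
               [s.species for s in self.fastq_species]

    @classmethod
    def from_ini(cls, path) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        read = cp.read(str(path))
        if not read:
            raise ParameterError(f"config file not found: {path}")
        g = cp["global"] if cp.has_section("global") else {}
        cfg = cls(outdir=g.get("outdir", "satlib_out"),
                  seed=int(g.get("seed", 1)))
        cfg.consensus_path = g.get("consensus") or None
        if g.get("subsample"):
            cfg.subsample = int(g["subsample"])
        for name, cast in (("min_overlap", int), ("min_aligned", int),
                           ("max_mismatch_frac", float), ("min_identity", float),
                           ("extract_identity", float), ("length_tol", float),
                           ("cluster_threshold", float)):
            if g.get(name):
                setattr(cfg, name, cast(g[name]))
        for name in ("singleton_filter", "cluster_pcr"):
            if g.get(name):
                setattr(cfg, name, g[name].strip().lower() in ("1", "true", "yes"))
        if cp.has_section("library"):
            lib = cp["library"]
            cfg.library_haplotypes = int(lib.get("n_haplotypes", cfg.library_haplotypes))
            cfg.library_unit_length = int(lib.get("unit_length", cfg.library_unit_length))
            cfg.library_divergence = float(lib.get("divergence", cfg.library_divergence))
        for section in cp.sections():
            if section.startswith("simulate:"):
                s = cp[section]
                species = section.split(":", 1)[1]
                weights = [float(x) for x in s["weights"].split(",")]
                profile = satsim.SpeciesProfile(
                    species, weights, int(s.get("copies", 100)),
                    mutation_rate=float(s.get("mutation_rate", 0.0)),
                    indel_rate=float(s.get("indel_rate", 0.0)),
                    exact_proportions=s.get("exact_proportions", "false").lower()
                    in ("1", "true", "yes"))
                cfg.sim_species.append(SimSpecies(
                    profile,
                    n_pairs=int(s.get("n_pairs", 2000)),
                    read_length=int(s.get("read_length", 250)),
                    frag_mean=int(s.get("frag_mean", 400)),
                    frag_sd=float(s.get("frag_sd", 25.0)),
                    error_rate=float(s.get("error_rate", 0.0))))
            elif section.startswith("input:"):
                s = cp[section]
                species = section.split(":", 1)[1]
                cfg.fastq_species.append(FastqSpecies(species, s["r1"], s["r2"]))
                if s.get("pcr"):
                    cfg.pcr_fastas[species] = s["pcr"]
        return cfg

    def to_ini(self, path) -> None:
        cp = configparser.ConfigParser()
        cp["global"] = {
            "outdir": str(self.outdir), "seed": str(self.seed),
            "consensus": self.consensus_path or "",
            "subsample": "" if self.subsample is None else str(self.subsample),
            "min_overlap": str(self.min_overlap),
            "max_mismatch_frac": str(self.max_mismatch_frac),
            "min_identity": str(self.min_identity),
            "min_aligned": str(self.min_aligned),
            "extract_identity": str(self.extract_identity),
            "length_tol": str(self.length_tol),
            "cluster_threshold": str(self.cluster_threshold),
            "singleton_filter": str(self.singleton_filter).lower(),
            "cluster_pcr": str(self.cluster_pcr).lower(),
        }
        if self.sim_species:
            cp["library"] = {"n_haplotypes": str(self.library_haplotypes),
                             "unit_length": str(self.library_unit_length),
                             "divergence": str(self.library_divergence)}
        for s in self.sim_species:
            p = s.profile
            cp[f"simulate:{p.species}"] = {
                "weights": ",".join(str(w) for w in p.amplification_weights),
                "copies": str(p.total_copies),
                "mutation_rate": str(p.mutation_rate),
                "indel_rate": str(p.indel_rate),
                "exact_proportions": str(p.exact_proportions).lower(),
                "n_pairs": str(s.n_pairs), "read_length": str(s.read_length),
                "frag_mean": str(s.frag_mean), "frag_sd": str(s.frag_sd),
                "error_rate": str(s.error_rate)}
        for s in self.fastq_species:
            sec = {"r1": s.r1, "r2": s.r2}
            if s.species in self.pcr_fastas:
                sec["pcr"] = self.pcr_fastas[s.species]
            cp[f"input:{s.species}"] = sec
        with open(path, "w") as out:
            cp.write(out)


@dataclass
class ReportBundle:
    stats: list[popstats.DiversityStats]
    haplotype_table: HaplotypeTable
    cluster_set: hapnet.ClusterSet | None
    mst: hapnet.MSTGraph | None
    funnel: pd.DataFrame
    outdir: Path


def _funnel_row(species):
    return {"species": species, "pairs_total": 0, "pairs_used": 0,
            "merged": 0, "homologous": 0, "reads_with_monomers": 0,
            "monomers": 0, "haplotypes": 0}


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages and write the report bundle under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    log_lines: list[str] = []

    def log(stage, msg):
        line = f"{time.strftime('%Y-%m-%d %H:%M:%S')} [{stage}] {msg}"
        logger.info("[%s] %s", stage, msg)
        log_lines.append(line)

    config.to_ini(outdir / "config.ini")

    # --- consensus / simulation setup -----------------------------------
    library = None
    if config.sim_species:
        library = satsim.simulate_library(
            config.library_haplotypes, config.library_unit_length,
            config.library_divergence, seed=config.seed + _SEED_LIBRARY)
        consensus = SatConsensus(
            f"SimSat01-{config.library_unit_length}", library.sequences[0])
        consensus.to_fasta(outdir / "consensus.fasta")
        log("simulate", f"ancestral library: {len(library)} haplotypes, "
            f"unit {config.library_unit_length} nt, divergence {config.library_divergence}")
    elif config.consensus_path:
        consensus = SatConsensus.from_fasta(config.consensus_path)
    else:
        raise PipelineError("config", "need a consensus FASTA or simulated species")

    funnel_rows = []
    all_monomers: list[Monomer] = []
    ground_truth: dict[str, list[satsim.SimMonomer]] = {}

    species_jobs: list[tuple[str, object]] = \
        [(s.profile.species, s) for s in config.sim_species] + \
        [(s.species, s) for s in config.fastq_species]

    for sp_idx, (species, job) in enumerate(species_jobs):
        row = _funnel_row(species)
        try:
            # -- reads ----------------------------------------------------
            if isinstance(job, SimSpecies):
                pool = satsim.amplify_species(library, job.profile,
                                              seed=config.seed + _SEED_AMPLIFY + sp_idx)
                ground_truth[species] = pool
                array = satsim.build_tandem_array(pool,
                                                  seed=config.seed + _SEED_ARRAY + sp_idx)
                satsim.write_ground_truth_tsv(array, outdir / f"{species}.truth.tsv")
                reads = satsim.generate_reads(
                    array.sequence, job.n_pairs, job.read_length,
                    job.frag_mean, job.frag_sd, job.error_rate,
                    seed=config.seed + _SEED_READS + sp_idx, id_prefix=f"{species}_")
                pairs = list(reads.pairs)
            else:
                pairs = list(readprep.read_pairs(job.r1, job.r2))
            if not pairs:
                raise DataError(f"no read pairs for species {species}")
            row["pairs_total"] = len(pairs)

            # -- subsample --------------------------------------------------
            if config.subsample is not None and config.subsample < len(pairs):
                pairs = readprep.subsample_pairs(
                    pairs, config.subsample,
                    seed=config.seed + _SEED_SUBSAMPLE + sp_idx)
            row["pairs_used"] = len(pairs)
            log("readprep", f"{species}: {row['pairs_total']} pairs in, "
                f"{row['pairs_used']} used")
        except SatlibError as exc:
            _write_funnel(funnel_rows + [row], outdir)
            _flush_log(log_lines, log_path)
            if isinstance(exc, PipelineError):
                raise
            raise PipelineError("readprep", str(exc)) from exc

        try:
            merged = []
            for p in pairs:
                m = readprep.merge_pair(p, config.min_overlap, config.max_mismatch_frac)
                if m is not None:
                    merged.append(m)
            row["merged"] = len(merged)

            hits = readprep.select_homologous(
                [(m.id, m.sequence) for m in merged], consensus,
                config.min_identity, config.min_aligned)
            hit_strand = {h.query_id: h.strand for h in hits}
            homologous = [m for m in merged if m.id in hit_strand]
            row["homologous"] = len(homologous)
            readprep.write_merged_fasta(homologous, outdir / f"{species}.merged.fasta")
            readprep.write_hits_tsv(hits, outdir / f"{species}.hits.tsv")
            log("readprep", f"{species}: merged {row['merged']}, "
                f"homologous {row['homologous']}")
        except SatlibError as exc:
            _write_funnel(funnel_rows + [row], outdir)
            _flush_log(log_lines, log_path)
            raise PipelineError("readprep", str(exc)) from exc

        try:
            sp_monomers = []
            reads_with = 0
            for m in homologous:
                seq = m.sequence if hit_strand[m.id] == "+" else revcomp(m.sequence)
                units = monomers.extract_monomers(
                    seq, consensus, config.extract_identity, config.length_tol,
                    source_id=m.id, species=species, origin="illumina",
                    check_reverse=False)
                if units:
                    reads_with += 1
                    sp_monomers.extend(units)
            row["reads_with_monomers"] = reads_with
            row["monomers"] = len(sp_monomers)
            if species in config.pcr_fastas:
                sp_monomers.extend(monomers.read_pcr_clones_fasta(
                    config.pcr_fastas[species], consensus, species))
            all_monomers.extend(sp_monomers)
            log("mine", f"{species}: {row['monomers']} monomers from "
                f"{reads_with} reads")
        except SatlibError as exc:
            _write_funnel(funnel_rows + [row], outdir)
            _flush_log(log_lines, log_path)
            raise PipelineError("mine", str(exc)) from exc
        funnel_rows.append(row)

    # --- tally + per-species stats ---------------------------------------
    try:
        table = monomers.tally_and_filter_singletons(
            all_monomers, apply_filter=config.singleton_filter)
        for row, species in zip(funnel_rows, [s for s, _ in species_jobs]):
            row["haplotypes"] = len(table.subset(species=species))
        table.to_tsv(outdir / "haplotypes.tsv")

        stats = []
        for species, origin in table.groups():
            sub = table.subset(species=species, origin=origin)
            aln = popstats.align_monomers(sub.sequences(), reference=consensus.sequence)
            stats.append(popstats.summarize(sub, aln, indel_policy=config.indel_policy))
            popstats.logo_matrix(aln, sub.counts()).to_csv(
                outdir / f"{species}.{origin}.logo.tsv", sep="\t", index=False)
        popstats.stats_frame(stats).to_csv(outdir / "diversity.tsv", sep="\t",
                                           index=False)
        log("stats", f"{len(stats)} (species, origin) diversity rows")
    except SatlibError as exc:
        _write_funnel(funnel_rows, outdir)
        _flush_log(log_lines, log_path)
        raise PipelineError("stats", str(exc)) from exc

    # --- clustering + MST -------------------------------------------------
    cluster_set = None
    mst = None
    try:
        if len(table) > 0:
            if config.cluster_pcr:
                cluster_rows = list(table.rows)
                pcr_rows = []
            else:
                cluster_rows = [r for r in table.rows if r.origin == "illumina"]
                pcr_rows = [r for r in table.rows if r.origin != "illumina"]
            cluster_set = hapnet.greedy_cluster(cluster_rows, config.cluster_threshold)
            cluster_set.to_frame().to_csv(outdir / "clusters.tsv", sep="\t", index=False)

            nodes: list[tuple[str, str, dict]] = []  # (label, sequence, attrs)
            seq_to_node: dict[str, int] = {}
            for c in cluster_set.clusters:
                seq_to_node[c.representative_seq] = len(nodes)
                nodes.append((c.representative_id, c.representative_seq,
                              {"species": c.species, "origin": c.origin,
                               "abundance": c.abundance}))
            for r in pcr_rows:
                if r.sequence in seq_to_node:
                    # same sequence seen in Illumina: keep illumina display origin
                    nodes[seq_to_node[r.sequence]][2]["abundance"] += r.count
                else:
                    nodes.append((r.haplotype_id, r.sequence,
                                  {"species": r.species, "origin": r.origin,
                                   "abundance": r.count}))
            labels = [n[0] for n in nodes]
            aln = popstats.align_monomers([n[1] for n in nodes],
                                          reference=consensus.sequence)
            dm = hapnet.pairwise_differences(aln)
            mst = hapnet.build_mst(dm, labels, {n[0]: n[2] for n in nodes})
            hapnet.export_graph(mst, outdir / "mst.gml", outdir / "mst.nodes.tsv")
            log("net", f"{len(cluster_set)} clusters, MST total weight "
                f"{mst.total_weight}")
    except SatlibError as exc:
        _write_funnel(funnel_rows, outdir)
        _flush_log(log_lines, log_path)
        raise PipelineError("net", str(exc)) from exc

    funnel = _write_funnel(funnel_rows, outdir)
    _flush_log(log_lines, log_path)
    return ReportBundle(stats, table, cluster_set, mst, funnel, outdir)


def _write_funnel(rows, outdir: Path) -> pd.DataFrame:
    funnel = pd.DataFrame(rows)
    funnel.to_csv(Path(outdir) / "funnel.tsv", sep="\t", index=False)
    return funnel


def _flush_log(lines, path) -> None:
    with open(path, "w") as out:
        out.write("\n".join(lines) + "\n")


def funnel_counts(bundle: ReportBundle) -> pd.DataFrame:
    """Per-species stage counts (reads in / merged / homologous / monomers)."""
    return bundle.funnel
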
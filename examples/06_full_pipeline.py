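"""End-to-end run: two simulated species sharing part of one satellite library.

Species A amplifies haplotypes 1-3 of the shared library, species B amplifies
haplotypes 2-4; the pipeline merges reads, selects satellite fragments, mines
monomers, summarizes diversity per species and links all haplotypes in one
minimum spanning tree. Equivalent shell command:

    satlib run --config <file>   (see PipelineConfig.to_ini)
"""
from pathlib import Path

from satlib import PipelineConfig, SimSpecies, SpeciesProfile, run_pipeline
from satlib.popstats import stats_frame

outdir = Path("scratch/example_pipeline")
config = PipelineConfig(
    outdir=str(outdir), seed=12,
    library_haplotypes=4, library_divergence=0.04,
    sim_species=[
        SimSpecies(SpeciesProfile("species_A", [0.6, 0.3, 0.1, 0.0], 100,
                                  exact_proportions=True), n_pairs=1200),
        SimSpecies(SpeciesProfile("species_B", [0.0, 0.1, 0.3, 0.6], 100,
                                  exact_proportions=True), n_pairs=1200),
    ])

bundle = run_pipeline(config)
print("stage funnel (reads in -> merged -> homologous -> monomers):")
print(bundle.funnel.to_string(index=False))
print("\nper-species diversity (the published-table layout):")
print(stats_frame(bundle.stats).to_string(index=False))
print(f"\nclusters: {len(bundle.cluster_set)}; MST weight: "
      f"{bundle.mst.total_weight} mutational steps")
print(f"report bundle written to {outdir}/ (TSV tables, GML tree, run log)")
print("  -> both species carry the shared haplotypes 2-3, so their nodes are"
      " linked in one connected tree, as the library hypothesis predicts")
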
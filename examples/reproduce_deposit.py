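"""Reproduce the published honey bee literature analysis from the deposit.

Requires the deposited Scopus export (doi:10.5281/zenodo.3379018) saved
as ``data/scopus_apis_mellifera.csv`` (and, if available, its curated
synonym table as ``data/synonyms.tsv``).  Expected with the full deposit:
14,113 records (5,640 pre-2006 / 8,473 post-2006), growth 0.087/yr
doubling every 7.97 years, top dendrogram split at 1991/1992, and
keyword-network transitivity 0.53 pre-2006 vs 0.44 post-2006.
"""

from pathlib import Path

from beelit import PipelineConfig, run

DATA = Path(__file__).resolve().parents[1] / "data"

config = PipelineConfig(
    corpus_csv=str(DATA / "scopus_apis_mellifera.csv"),
    synonym_tsv=str(DATA / "synonyms.tsv") if (DATA / "synonyms.tsv").exists() else None,
    boundary_year=2006,
    min_pubs_per_year=5,
    top_k=50,
    n_boot=1000,
    k_grid=[20, 50, 70, 90, 110, 140],
    chosen_k=20,
    seed=0,
    outdir="deposit_run",
)
bundle = run(config)

print(f"records: {bundle['n_records']} "
      f"({bundle['n_pre']} pre-2006 / {bundle['n_post']} post-2006)")
fit = bundle["growth_fit"]
print(f"growth {fit.b:.3f}/yr (R^2 {fit.r_squared:.2f}, n {fit.n}), "
      f"doubling every {fit.doubling_time:.2f} yr")
early, late = sorted(bundle["clustering"].top_split(), key=min)
print(f"top year-cluster split: {max(early)} | {min(late)}")
print("keyword transitivity:", bundle["keyword_transitivity"])
print("topic transitivity:  ", bundle["topic_transitivity"])
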
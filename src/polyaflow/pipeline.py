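"""End-to-end orchestration and report emission.

``run_pipeline`` chains curation -> clustering -> assignment -> profiles
(-> EST validation -> conservation when the corresponding inputs are
given) and writes paper-shaped TSV reports, updated-annotation GFF3 files
and a JSON run manifest.  Every number in a report is recomputable from
the intermediate files emitted next to it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation, assignment, clustering, conservation, curation, profiles
from .params import Parameters, species_profile

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome: str | None = None
    annotation: str | None = None
    tags: str | None = None
    ests: str | None = None            # BED of EST-derived poly(A) sites
    ortholog_table: str | None = None  # TSV with gene_a/gene_b + feature flags
    species: str = "mtr_like"          # mtr_like | ath_like | custom
    parameter_overrides: dict = field(default_factory=dict)
    outdir: str = "polyaflow_out"
    seed: int = 0
    verbosity: int = 1

    def resolve_params(self) -> Parameters:
        return species_profile(self.species, **self.parameter_overrides)


def _read_est_bed(path):
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, *rest = line.split("\t")
            strand = rest[2] if len(rest) >= 3 else "+"
            pos = int(start) if strand == "-" else int(end) - 1
            sites.append((chrom, strand, pos))
    return sites


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest dict (also written to disk)."""
    t0 = time.monotonic()
    params = config.resolve_params()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"parameters": dataclasses.asdict(params),
                "species": config.species, "seed": config.seed,
                "stages": {}, "failure": None}

    def fail(stage, exc):
        manifest["failure"] = {"stage": stage, "error": str(exc)}
        _write_manifest(manifest, outdir)
        raise

    for name in ("genome", "annotation", "tags"):
        if getattr(config, name) is None:
            raise SystemExit(f"missing mandatory input: {name}")

    from .simulate import read_fasta

    genome = read_fasta(config.genome)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    models = annotation.read_gene_models(config.annotation, chrom_lengths, params)
    manifest["stages"]["annotation"] = {"n_genes": len(models)}
    annotation.write_gene_models_gff3(models.values(), outdir / "gene_models.gff3")

    # --- curation ---
    try:
        raw = curation.read_tags_bed(config.tags)
        kept, discarded, report = curation.curate_tags(raw, genome, params)
        curation.write_tags_bed(kept, outdir / "tags_kept.bed")
        curation.write_tags_bed(discarded, outdir / "tags_internal_priming.bed")
        (outdir / "curation_report.tsv").write_text(report.to_tsv())
        manifest["stages"]["curation"] = dataclasses.asdict(report)
    except SystemExit:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        fail("curation", exc)

    if not kept:
        log.warning("no curated tags; emitting empty reports")
        _write_empty_reports(outdir)
        manifest["stages"]["clustering"] = {"n_pacs": 0}
        _write_manifest(manifest, outdir)
        return manifest

    # --- clustering ---
    pacs = clustering.cluster_tags(kept, params)
    clustering.write_pacs_gff3(pacs, outdir / "pacs.gff3")
    clustering.write_pacs_bed(pacs, outdir / "pacs.bed")
    singles, multis = clustering.single_tag_pac_partition(pacs)
    manifest["stages"]["clustering"] = {"n_pacs": len(pacs),
                                        "n_single_pat": len(singles),
                                        "n_multi_pat": len(multis)}

    # --- assignment ---
    index = annotation.GenomeIndex(models.values())
    assign = assignment.assign_all(pacs, index, params)
    assign.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    assignment.tabulate_sense(assign).to_csv(outdir / "table_sense_regions.tsv",
                                             sep="\t", index=False)
    assignment.tabulate_antisense(assign).to_csv(outdir / "table_antisense_cases.tsv",
                                                 sep="\t", index=False)
    per_gene, marginal, frac_multi = clustering.pacs_per_gene(assign)
    (outdir / "table_pacs_per_gene.tsv").write_text(clustering.apa_table_tsv(marginal))
    inter = assignment.intergenic_distances(assign, index, params)
    manifest["stages"]["assignment"] = {
        "n_assignment_rows": len(assign),
        "n_genes_with_pac": int(per_gene.shape[0]),
        "frac_genes_multi_pac": frac_multi,
        "n_intergenic": inter["n_intergenic"],
        "frac_intergenic_beyond_1000": inter["frac_beyond_threshold"],
    }

    # --- profiles ---
    prof = profiles.stratified_profiles(pacs, assign, genome, params)
    for (stratum, support), p in prof.items():
        fname = f"profile_{stratum}_{support.replace('-PAT', '')}.tsv"
        p.to_frame().to_csv(outdir / fname, sep="\t", index=False)
    manifest["stages"]["profiles"] = {"n_strata": len(prof)}

    # --- EST validation ---
    if config.ests:
        est_sites = _read_est_bed(config.ests)
        rep = conservation.est_validation(est_sites, pacs, params)
        manifest["stages"]["est_validation"] = {
            "n_est_sites": rep.n_est_sites, "n_validated": rep.n_validated,
            "pct_validated": rep.pct_validated}
        (outdir / "est_validation.tsv").write_text(
            "n_est_sites\tn_validated\tpct_validated\n"
            f"{rep.n_est_sites}\t{rep.n_validated}\t{rep.pct_validated:.1f}\n")

    # --- conservation (needs a second-species ortholog/feature table) ---
    if config.ortholog_table:
        table = pd.read_csv(config.ortholog_table, sep="\t")
        results = conservation_from_table(table, params, seed=config.seed)
        rows = [dataclasses.asdict(r) for r in results]
        pd.DataFrame(rows).to_csv(outdir / "conservation_results.tsv",
                                  sep="\t", index=False)
        manifest["stages"]["conservation"] = {
            r["feature"]: {"observed_shared": r["observed_shared"],
                           "expected_mean": r["expected_mean"],
                           "p_value": r["p_value"]} for r in rows}

    manifest["runtime_s"] = round(time.monotonic() - t0, 3)
    _write_manifest(manifest, outdir)
    return manifest


def conservation_from_table(table: pd.DataFrame, params: Parameters, seed: int = 0):
    """Run the randomization conservation test for every feature-flag pair in
    an ortholog table with ``<feature>_a`` / ``<feature>_b`` Boolean columns."""
    feats = sorted({c[:-2] for c in table.columns if c.endswith("_a")
                    and f"{c[:-2]}_b" in table.columns})
    pairs = list(zip(table["gene_a"], table["gene_b"]))
    pool = list(table["gene_a"])
    results = []
    for feat in feats:
        fa = set(table.loc[table[f"{feat}_a"].astype(bool), "gene_a"])
        fb = set(table.loc[table[f"{feat}_b"].astype(bool), "gene_b"])
        results.append(conservation.feature_conservation_test(
            fb, pairs, fa, pool, params, seed=seed, feature=feat))
    return results


def _write_manifest(manifest: dict, outdir: Path) -> None:
    stable = dict(manifest)
    stable.pop("runtime_s", None)  # keep manifests byte-identical across runs
    (outdir / "manifest.json").write_text(
        json.dumps(stable, indent=1, sort_keys=True) + "\n")


def _write_empty_reports(outdir: Path) -> None:
    (outdir / "pacs.bed").write_text("")
    (outdir / "assignments.tsv").write_text(
        "pac_id\tchrom\tstrand\tsummit\ttag_count\tgene_id\tregion\t"
        "orientation\tantisense_case\tdistance_to_nearest_gene_end\n")
    (outdir / "table_pacs_per_gene.tsv").write_text(clustering.apa_table_tsv({}))
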
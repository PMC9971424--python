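"""End-to-end workflow: classify -> metrics -> ICA -> diagnostics ->
resampling -> optional Ka/Ks, with TSV/JSON reports.

All stages are thin orchestration over the library modules; the run writes
its resolved configuration next to its outputs and logs one structured
line per stage.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import codon_metrics, diagnostics, ica, resampling
from .gene_catalog import CatalogConfig, bin_chromosomes, flank_gc, load_catalog

logger = logging.getLogger(__name__)

GC3_THRESHOLDS = (0.8, 0.7, 0.6, 0.5)
EXPRESSION_THRESHOLDS = (2.0, 0.65, 0.3, 0.13)


@dataclass
class RunConfig:
    fasta: str
    gff3: str
    out_dir: str
    expression: str | None = None       # TSV gene_id -> expression
    kaks_pairs: dict | None = None      # pair_id -> (seq1, seq2)
    min_cds_len: int = 300
    flank: int = 200
    codons: int = 59
    n_iter: int = 1000
    seed: int = 0
    n_bins: int = 10

    def to_json(self) -> str:
        d = asdict(self)
        d["kaks_pairs"] = sorted(self.kaks_pairs) if self.kaks_pairs else None
        return json.dumps(d, indent=2, sort_keys=True)


def _stage(name: str, t0: float, **counts) -> None:
    info = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0, info)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns a dict of output paths/objects."""
    fasta, gff3 = Path(config.fasta), Path(config.gff3)
    if not fasta.exists():
        raise FileNotFoundError(f"FASTA not found: {fasta}")
    if not gff3.exists():
        raise FileNotFoundError(f"GFF3 not found: {gff3}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    t0 = time.time()
    catalog = load_catalog(fasta, gff3, CatalogConfig(config.min_cds_len, config.flank))
    catalog.write_tsv(out / "gene_table.tsv")
    catalog.write_cds_fasta(out / "cds.fa")
    n_total = len(catalog.records)
    n_kept = len(catalog.retained)
    n_excl = sum(1 for r in catalog.records if r.label == "EXCLUDED")
    assert n_kept + n_excl == n_total, "count conservation violated"
    _stage("classify", t0, parsed=n_total, retained=n_kept, excluded=n_excl)
    bundle["catalog"] = catalog

    t0 = time.time()
    cds = catalog.cds_by_gene()
    gcf = {r.gene_id: flank_gc(r) for r in catalog.retained}
    profiles = codon_metrics.profile_table(cds, gcf_by_gene=gcf)
    profiles["label"] = pd.Series({r.gene_id: r.label for r in catalog.retained})
    profiles.to_csv(out / "profiles.tsv", sep="\t")
    regions = bin_chromosomes(catalog, config.n_bins)
    regions.to_csv(out / "regions.tsv", sep="\t", index=False)
    _stage("metrics", t0, genes=len(profiles))
    bundle["profiles"] = profiles

    t0 = time.time()
    counts = codon_metrics.codon_count_matrix(cds)
    groupings = {"gene_type": profiles["label"]}
    gc3_groups = diagnostics.make_groups(profiles["gc3s"], GC3_THRESHOLDS)
    groupings["gc3"] = gc3_groups.labels
    if config.expression is not None:
        expr = pd.read_csv(config.expression, sep="\t", index_col=0).iloc[:, 0]
        expr = expr.reindex(profiles.index).dropna()
        sizes = [gc3_groups.sizes[k] for k in sorted(gc3_groups.sizes)]
        try:
            expr_groups = diagnostics.make_groups(
                expr, EXPRESSION_THRESHOLDS,
                matched_sizes=sizes if sum(sizes) == len(expr) else None)
            groupings["expression"] = expr_groups.labels
        except ValueError as exc:
            logger.warning("expression grouping skipped: %s", exc)
    ica_reports = {}
    for name, grouping in groupings.items():
        try:
            table = ica.build_table(counts, grouping, codons=config.codons)
        except ValueError as exc:
            logger.warning("ICA grouping %s skipped: %s", name, exc)
            continue
        dec = ica.ica_decompose(table)
        (out / f"ica_{name}.json").write_text(json.dumps(dec.to_dict(), indent=2))
        ica_reports[name] = dec
        bundle.setdefault("tables", {})[name] = table
    _stage("ica", t0, groupings=len(ica_reports))
    bundle["ica"] = ica_reports

    t0 = time.time()
    seg = profiles[profiles["label"] == "SEG"]
    meg = profiles[profiles["label"] == "MEG"]
    deviations, fits, below = diagnostics.enc_plot(
        profiles["enc"], profiles["gc3s"], profiles["label"])
    deviations.rename("enc_deviation").to_frame().to_csv(
        out / "enc_deviation.tsv", sep="\t")
    diag = {
        "enc_plot": {
            lbl: {"fit": f.to_dict() if f else None, "below_curve": below[lbl]}
            for lbl, f in fits.items()
        }
    }
    if len(seg) >= 3 and len(meg) >= 3:
        fit_seg = diagnostics.neutrality_fit(seg["gc12"], seg["gc3"])
        fit_meg = diagnostics.neutrality_fit(meg["gc12"], meg["gc3"])
        diag["neutrality"] = {
            "SEG": fit_seg.to_dict(), "MEG": fit_meg.to_dict(),
            "slope_difference_p": diagnostics.compare_slopes(
                seg["gc3"], seg["gc12"], meg["gc3"], meg["gc12"]),
        }
    (out / "diagnostics.json").write_text(json.dumps(diag, indent=2))
    _stage("diagnostics", t0)
    bundle["diagnostics"] = diag

    t0 = time.time()
    resample_reports = {}
    if "gene_type" in bundle.get("tables", {}):
        table = bundle["tables"]["gene_type"]
        sizes = table.row_class.value_counts()
        resample_reports["subsample"] = resampling.subsample_null(
            table, int(sizes.min()), config.n_iter, config.seed)
        resample_reports["label_permutation"] = resampling.label_permutation(
            table, config.n_iter, config.seed)
        for name, res in resample_reports.items():
            (out / f"resample_{name}.json").write_text(
                json.dumps(res.to_dict(), indent=2))
    _stage("resampling", t0, reports=len(resample_reports))
    bundle["resampling"] = resample_reports

    if config.kaks_pairs:
        t0 = time.time()
        from .kaks import kaks_table

        kk = kaks_table(config.kaks_pairs)
        kk.to_csv(out / "kaks.tsv", sep="\t")
        _stage("kaks", t0, pairs=len(kk))
        bundle["kaks"] = kk

    (out / "run_config.json").write_text(config.to_json())
    return bundle
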
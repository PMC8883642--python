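"""End-to-end orchestration: regions -> normalization -> MVC -> estimation
-> testing, with proximal and distal strata handled separately by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import estimation, mvc, normalization, regions, testing

logger = logging.getLogger("hypervar")


class PipelineError(RuntimeError):
    """Raised with the name of the failing stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    counts_path: str = ""
    occupancy_path: str = ""
    tss_path: str | None = None
    out_dir: str = "hypervar_out"
    proximal_cutoff: int = 5000
    span: float = mvc.DEFAULT_SPAN
    fraction: float = estimation.DEFAULT_FRACTION
    p_l: float = estimation.DEFAULT_P_LOWER
    p_u: float = estimation.DEFAULT_P_UPPER
    fdr_cutoff: float = 0.1
    stratified: bool = True
    drop_sex: bool = True
    seed: int = 0
    extra: dict = field(default_factory=dict)


def _parse_region_ids(ids) -> regions.RegionSet:
    regs = []
    for rid in ids:
        try:
            chrom, rest = rid.rsplit(":", 1)
            start, end = rest.split("-")
            regs.append(regions.GenomicRegion(chrom, int(start), int(end)))
        except (ValueError, TypeError):
            raise PipelineError(
                "input-validation", f"region id {rid!r} is not 'chrom:start-end'"
            ) from None
    return regions.RegionSet(regs)


def analyse_stratum(
    counts: pd.DataFrame,
    occ: pd.DataFrame,
    config: PipelineConfig,
    stratum: str = "unassigned",
) -> tuple[testing.RegionTestResult, estimation.ModelFit, mvc.MeanVarianceCurve]:
    """Run normalization, MVC fitting, moment estimation and testing on one
    stratum's matrices."""
    x, _ = normalization.normalize_all(counts, occ)
    table = mvc.mean_variance(x)
    curve = mvc.fit_mvc(table, span=config.span)
    table = mvc.scaled_variances(table, curve)
    fit = estimation.fit_model(
        table, curve, fraction=config.fraction, p_l=config.p_l, p_u=config.p_u
    )
    result = testing.test_regions(table, fit, stratum=stratum)
    result = testing.call_regions(result, cutoff=config.fdr_cutoff)
    return result, fit, curve


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole workflow from count/occupancy tables to called regions.

    Writes one result TSV per stratum, the model fit summary, the fitted MVC
    and a JSON run manifest into ``config.out_dir``; returns the manifest.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        counts = regions.read_matrix(config.counts_path)
        occ = regions.read_matrix(config.occupancy_path, binary=True)
    except (OSError, regions.MatrixFormatError) as err:
        raise PipelineError("input-validation", str(err)) from None
    if counts.shape != occ.shape or list(counts.index) != list(occ.index) or list(
        counts.columns
    ) != list(occ.columns):
        raise PipelineError(
            "input-validation", "count and occupancy matrices do not align"
        )
    rset = _parse_region_ids(counts.index)
    if len(rset) != counts.shape[0]:
        raise PipelineError("input-validation", "duplicate or unsorted region ids")

    if config.drop_sex:
        keep = [not regions._is_sex_chrom(r.chrom) for r in rset]
        ids = [r.id for r, k in zip(rset, keep) if k]
        counts, occ = counts.loc[ids], occ.loc[ids]
        rset = _parse_region_ids(counts.index)

    strata: dict[str, list[str]] = {}
    if config.stratified and config.tss_path:
        tss = regions.read_tss(config.tss_path)
        rset = regions.classify_proximal_distal(
            rset, tss, cutoff=config.proximal_cutoff
        )
        frame = regions.region_set_to_frame(rset)
        for name in (regions.PROXIMAL, regions.DISTAL):
            ids = list(frame.index[frame["stratum"] == name])
            if ids:
                strata[name] = ids
    else:
        strata["all"] = list(counts.index)

    manifest = {"config": {k: v for k, v in asdict(config).items()}, "strata": {}}
    for name, ids in strata.items():
        logger.info("analysing stratum %s (%d regions)", name, len(ids))
        if len(ids) < 50:
            raise PipelineError("estimation", f"stratum {name!r} too small")
        try:
            result, fit, curve = analyse_stratum(
                counts.loc[ids], occ.loc[ids], config, stratum=name
            )
        except normalization.DegenerateSampleError as err:
            raise PipelineError("normalization", str(err)) from None
        except ValueError as err:
            raise PipelineError("estimation", str(err)) from None
        res_path = out_dir / f"results_{name}.tsv"
        result.table.round(10).to_csv(res_path, sep="\t")
        curve.to_frame().round(10).to_csv(
            out_dir / f"mvc_{name}.tsv", sep="\t", index=False
        )
        with open(out_dir / f"model_fit_{name}.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=2)
        calls = result.table["call"].value_counts().to_dict()
        manifest["strata"][name] = {
            "n_regions": len(ids),
            "model_fit": fit.to_dict(),
            "calls": calls,
            "results": str(res_path),
        }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
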
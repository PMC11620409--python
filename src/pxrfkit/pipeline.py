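"""End-to-end pipeline: ingest -> panel QC -> LOD filter -> thickness QC ->
variation tests -> replicate precision -> summary.

Every output CSV carries a comment header recording the stage, the config
hash and the seed, so any table can be traced to the exact run that made
it.  Stages are content-addressed: when a stage's outputs already exist and
were produced from the same config hash, the stage is skipped on re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io_vanta, stats, thickness, validation
from .lines import ATOMIC_NUMBER, default_line_table
from .stats import ComparisonSkipped, TestResult

__all__ = ["RunConfig", "run_pipeline", "run_variation_tests"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    input_dir: str
    output_dir: str
    snr_threshold: float = 3.0
    thickness_threshold: float = 0.10
    n_perm: int = 999
    seed: int = 1
    alpha: float = 0.05
    transform: str = "log"
    min_detects_per_group: int = 3
    aggregate_replicates: bool = False
    state_for_location_test: str = field(default="thawed")

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.transform not in ("log", "none"):
            raise ValueError("transform must be 'log' or 'none'")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        analysis of the same inputs hashes identically anywhere)."""
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("input_dir", "output_dir")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, stage: str, cfg: RunConfig) -> None:
    header = (
        f"# stage={stage}\n"
        f"# config_hash={cfg.config_hash()}\n"
        f"# seed={cfg.seed}\n"
    )
    path.write_text(header + df.to_csv(index=False))


def _read_stage_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _results_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = asdict(r)
        d["n_per_group"] = "/".join(str(n) for n in r.n_per_group)
        rows.append(d)
    return pd.DataFrame(rows)


def _maybe_aggregate(df: pd.DataFrame, aggregate: bool) -> pd.DataFrame:
    if not aggregate:
        return df
    keys = ["specimen_id", "taxon", "location", "state", "dwell_time_s", "backed", "element"]
    agg = (
        df.groupby(keys, observed=True, as_index=False)
        .agg(concentration_pct=("concentration_pct", "mean"),
             below_lod=("below_lod", "all"))
    )
    agg["replicate"] = 1
    return agg


def _factor_tests(
    df: pd.DataFrame,
    factor: str,
    group_col: str,
    cfg: RunConfig,
    taxon: str,
    context: str,
) -> list[TestResult]:
    """Overall + per-element tests of one factor within one taxon subset."""
    results: list[TestResult] = []
    filtered = validation.apply_lod_filter(df, group_col, cfg.min_detects_per_group)
    if filtered.empty:
        logger.info("%s %s: nothing left after LOD filtering", taxon, factor)
        return results
    levels = list(pd.unique(filtered[group_col]))
    if len(levels) < 2:
        return results
    tag = hashlib.sha256(f"{taxon}|{factor}|{context}".encode()).digest()
    seed_base = (cfg.seed * 100003 + int.from_bytes(tag[:4], "big") % 50021) % (2**31)

    # overall: complete-case wide matrix, one manyglm per level pair
    wide = filtered.pivot_table(
        index=["export_id", group_col], columns="element",
        values="concentration_pct", observed=True,
    )
    for i, (a, b) in enumerate(
        (la, lb) for j, la in enumerate(levels) for lb in levels[j + 1:]
    ):
        sub = wide[wide.index.get_level_values(group_col).isin([a, b])].dropna(axis=1)
        g = sub.index.get_level_values(group_col).to_numpy()
        if sub.shape[1] == 0 or min((g == a).sum(), (g == b).sum()) < 2:
            continue
        try:
            res = stats.manyglm_overall(
                sub.to_numpy(), g, transform=cfg.transform,
                n_perm=cfg.n_perm, seed=seed_base + i,
                factor=factor, comparison=f"{a} vs {b}", taxon=taxon,
            )
            results.append(res)
        except ValueError as exc:
            logger.info("%s %s overall %s vs %s skipped: %s", taxon, factor, a, b, exc)

    # per element: pairwise median permutation tests, BH within element family
    element_results: list[TestResult] = []
    for element, sub in filtered.groupby("element", observed=True):
        try:
            element_results.extend(
                stats.pairwise_comparisons(
                    sub["concentration_pct"].to_numpy(), sub[group_col].to_numpy(),
                    n_perm=cfg.n_perm, seed=seed_base + 1000 + ATOMIC_NUMBER.get(element, 0),
                    factor=factor, scope=str(element), taxon=taxon,
                )
            )
        except (ValueError, ComparisonSkipped) as exc:
            logger.info("%s %s %s skipped: %s", taxon, factor, element, exc)
    # re-adjust BH across the whole per-element family for this factor/taxon
    if element_results:
        adj = stats.bh_adjust([r.p_value for r in element_results])
        for r, pa in zip(element_results, adj):
            r.p_adjusted = float(pa)
    results.extend(element_results)
    return results


def run_variation_tests(table: pd.DataFrame, cfg: RunConfig) -> dict[str, list[TestResult]]:
    """The paper-style battery: state, scan-time and location tests, run per
    taxon (state and scan-time within each scan location)."""
    out: dict[str, list[TestResult]] = {"state": [], "scan_time": [], "location": []}
    for taxon, tdf in table.groupby("taxon", observed=True):
        # sample state: thawed vs dried, within each location
        if tdf["state"].nunique() > 1:
            for location, ldf in tdf.groupby("location", observed=True):
                out["state"].extend(
                    _factor_tests(ldf, "state", "state", cfg, str(taxon), f"loc={location}")
                )
        # scan time: pairwise dwell comparisons, within each location
        if tdf["dwell_time_s"].nunique() > 1:
            for location, ldf in tdf.groupby("location", observed=True):
                out["scan_time"].extend(
                    _factor_tests(
                        ldf, "scan_time", "dwell_time_s", cfg, str(taxon), f"loc={location}"
                    )
                )
        # scan location: pairwise location comparisons within one state
        state = cfg.state_for_location_test
        sdf = tdf[tdf["state"] == state]
        if sdf.empty:  # taxa never thawed (feathers) use their natural state
            sdf = tdf[tdf["state"] == "natural"]
        if sdf["location"].nunique() > 1:
            out["location"].extend(
                _factor_tests(sdf, "location", "location", cfg, str(taxon), "all")
            )
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns a run report dict.

    Stage order: ingest -> validate_panel -> LOD filter -> thickness QC ->
    per-factor tests -> replicate precision -> summary matrix.  Outputs are
    CSVs under cfg.output_dir; a manifest records the config hash so a rerun
    with identical config skips completed stages.
    """
    in_dir, out_dir = Path(cfg.input_dir), Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    chash = cfg.config_hash()
    manifest = {}
    if manifest_path.exists():
        try:
            manifest = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            manifest = {}
    if manifest.get("config_hash") != chash:
        manifest = {"config_hash": chash, "stages": {}}

    def stage_done(name: str, outputs: list[Path]) -> bool:
        return manifest["stages"].get(name) == chash and all(p.exists() for p in outputs)

    def mark(name: str) -> None:
        manifest["stages"][name] = chash
        manifest_path.write_text(json.dumps(manifest, indent=1))

    report: dict = {"config_hash": chash, "seed": cfg.seed, "stages": []}
    lines = default_line_table()

    # ---- ingest -------------------------------------------------------
    compiled = out_dir / "compiled.csv"
    records, table, skipped = io_vanta.ingest_directory(in_dir)
    if not stage_done("ingest", [compiled]):
        _write_csv(table, compiled, "ingest", cfg)
        mark("ingest")
    report["stages"].append({"stage": "ingest", "n_exports": len(records), "skipped": skipped})

    # ---- element panel ------------------------------------------------
    panel_csv, evidence_csv = out_dir / "panel.csv", out_dir / "evidence.csv"
    taxa = sorted({r.metadata.taxon for r in records})
    retained_by_taxon: dict[str, tuple[str, ...]] = {}
    if stage_done("panel", [panel_csv, evidence_csv]):
        pdf = _read_stage_csv(panel_csv)
        for taxon in taxa:
            sub = pdf[(pdf["taxon"] == taxon) & pdf["retained"]]
            retained_by_taxon[taxon] = tuple(sub["element"])
    else:
        panel_rows, evidence_frames = [], []
        for taxon in taxa:
            result = validation.validate_panel(
                records, lines, snr_threshold=cfg.snr_threshold, taxon=taxon
            )
            retained_by_taxon[taxon] = result.retained
            for element in result.retained:
                panel_rows.append({"taxon": taxon, "element": element, "retained": True})
            for element in result.excluded:
                panel_rows.append({"taxon": taxon, "element": element, "retained": False})
            ev = result.evidence.copy()
            ev.insert(0, "taxon", taxon)
            evidence_frames.append(ev)
        _write_csv(pd.DataFrame(panel_rows), panel_csv, "panel", cfg)
        _write_csv(pd.concat(evidence_frames, ignore_index=True), evidence_csv, "panel", cfg)
        mark("panel")
    report["stages"].append(
        {"stage": "panel",
         "retained": {t: len(v) for t, v in retained_by_taxon.items()}}
    )

    # ---- thickness QC -------------------------------------------------
    verdicts_csv = out_dir / "thickness_verdicts.csv"
    if stage_done("thickness", [verdicts_csv]):
        verdicts = _read_stage_csv(verdicts_csv)
    else:
        taxon_of = {r.metadata.specimen_id: r.metadata.taxon for r in records}
        verdicts = thickness.thickness_verdicts(
            records, threshold=cfg.thickness_threshold, lines=lines
        )
        verdicts.insert(0, "taxon", verdicts["specimen_id"].map(taxon_of))
        _write_csv(verdicts, verdicts_csv, "thickness", cfg)
        mark("thickness")
    report["stages"].append(
        {"stage": "thickness", "fraction_met": float(verdicts["met"].mean())}
    )

    # ---- variation tests ---------------------------------------------
    test_csvs = {f: out_dir / f"results_{f}.csv" for f in ("state", "scan_time", "location")}
    analysis = _maybe_aggregate(table, cfg.aggregate_replicates)
    # restrict each taxon to its validated panel
    frames = []
    for taxon, tdf in analysis.groupby("taxon", observed=True):
        frames.append(tdf[tdf["element"].isin(retained_by_taxon.get(str(taxon), ()))])
    analysis = pd.concat(frames, ignore_index=True) if frames else analysis.iloc[:0]

    if stage_done("tests", list(test_csvs.values())):
        families = {f: _read_stage_csv(p) for f, p in test_csvs.items()}
        all_results: list[TestResult] = []
        for fac, fdf in families.items():
            for _, row in fdf.iterrows():
                all_results.append(
                    TestResult(
                        factor=row["factor"], comparison=row["comparison"],
                        scope=row["scope"], estimate=row["estimate"],
                        statistic=row["statistic"], p_value=row["p_value"],
                        p_adjusted=row["p_adjusted"], method=row["method"],
                        taxon=row["taxon"],
                    )
                )
    else:
        families_lists = run_variation_tests(analysis, cfg)
        all_results = [r for fam in families_lists.values() for r in fam]
        for fac, path in test_csvs.items():
            _write_csv(_results_frame(families_lists[fac]), path, f"tests:{fac}", cfg)
        mark("tests")
    report["stages"].append(
        {"stage": "tests", "n_results": len(all_results)}
    )

    # ---- replicate precision ------------------------------------------
    precision_csv = out_dir / "precision.csv"
    precision = stats.replicate_precision(analysis) if not cfg.aggregate_replicates else []
    if precision and not stage_done("precision", [precision_csv]):
        pf = pd.DataFrame(
            [{"scope": p.scope, "rho": p.rho, "n_pairs": p.n_pairs} for p in precision]
        )
        _write_csv(pf, precision_csv, "precision", cfg)
        mark("precision")
    if precision:
        report["stages"].append(
            {"stage": "precision", "overall_rho": precision[0].rho}
        )

    # ---- summary ------------------------------------------------------
    summary_csv = out_dir / "summary_matrix.csv"
    summary = stats.summarize_study(all_results, verdicts, precision, alpha=cfg.alpha)
    _write_csv(summary, summary_csv, "summary", cfg)
    mark("summary")
    report["stages"].append({"stage": "summary", "path": str(summary_csv)})
    report["summary"] = summary.to_dict(orient="records")
    return report
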
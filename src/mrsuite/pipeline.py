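"""Orchestration: full univariable / bidirectional / multivariable MR runs
and the GSEA validation arm, from a single config, with published-table-
shaped report output.

The univariable chain per exposure-outcome contrast is

    p-filter -> dedup -> clump -> harmonize (palindrome drop) -> F-filter
    -> IVW, MR-Egger (+intercept), weighted median, RAPS, MR-PRESSO,
       Cochran's Q, leave-one-out

and each contrast becomes a block of report rows carrying Method, the
effect with its 95% CI formatted to 3 decimals (OR scale for binary
outcomes, beta scale otherwise), the p-value (starred when < 0.05), and
the diagnostic columns Q, P_h (heterogeneity p) and P_p (Egger intercept
p).  Inapplicable cells print NA rather than being dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mrsuite.gwas_io import GwasTable, read_gwas_table
from mrsuite.instruments import (
    LdMatrix,
    select_by_pvalue,
    drop_duplicates,
    greedy_clump,
    filter_by_f,
)
from mrsuite.harmonize import HarmonizedSet, harmonize
from mrsuite.estimators import (
    MrEstimate,
    ivw,
    egger,
    weighted_median,
    raps,
    to_or_scale,
)
from mrsuite.heterogeneity import cochran_q, leave_one_out
from mrsuite.presso import presso
from mrsuite.mvmr import MvmrInput, mvmr_ivw, mvmr_egger
from mrsuite.gsea import (
    ExpressionMatrix,
    moderated_t,
    rank_genes,
    enrichment_score,
    gsea_permutation,
    filter_significant,
    read_gmt,
)

REPORT_COLUMNS = [
    "exposure", "outcome", "n_snp", "method", "estimate",
    "pvalue", "Q", "P_h", "P_p",
]


@dataclass
class AnalysisConfig:
    """Resolved settings for one full run; defaults follow the standard
    instrument-selection thresholds (p <= 5e-6, r2 < 0.001 within
    10,000 kb, F >= 10)."""

    exposures: dict[str, str] = field(default_factory=dict)  # label -> path
    outcomes: dict[str, str] = field(default_factory=dict)
    ld_path: str | None = None
    direction: str = "forward"  # forward | reverse | both
    pval_threshold: float = 5e-6
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    min_f: float = 10.0
    estimators: tuple[str, ...] = ("ivw", "egger", "weighted_median", "raps")
    presso_n_sim: int = 1000
    presso_sig: float = 0.05
    wm_n_boot: int = 1000
    gsea_expression: str | None = None
    gsea_groups: str | None = None
    gsea_gmt: str | None = None
    gsea_n_perm: int = 1000
    gsea_min_size: int = 10
    gsea_max_size: int = 500
    gsea_export_sets: tuple[str, ...] = ()
    output_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def format_estimate(e: MrEstimate, or_scale: bool) -> str:
    """'x.xxx (l.lll–u.uuu)' on the requested scale."""
    if or_scale:
        e = to_or_scale(e)
        v, lo, hi = e.or_scale
    else:
        v, lo, hi = e.theta, e.ci_low, e.ci_high
    return f"{_fmt(v)} ({_fmt(lo)}–{_fmt(hi)})"


def _fmt_p(p: float) -> str:
    return f"{p:.3g}" + ("*" if p < 0.05 else "")


def select_instruments(
    table: GwasTable,
    ld: LdMatrix | None,
    cfg: AnalysisConfig,
) -> tuple[GwasTable, dict]:
    """p-filter -> dedup -> clump; returns the table and per-step counts."""
    log = {"input": len(table)}
    t = select_by_pvalue(table, cfg.pval_threshold)
    log["after_pvalue"] = len(t)
    t = drop_duplicates(t)
    log["after_dedup"] = len(t)
    t = greedy_clump(t, ld, r2_max=cfg.clump_r2, window_kb=cfg.clump_kb)
    log["after_clump"] = len(t)
    return t, log


def harmonized_instruments(
    exposure: GwasTable,
    outcome: GwasTable,
    ld: LdMatrix | None,
    cfg: AnalysisConfig,
) -> tuple[HarmonizedSet | None, dict]:
    """Full selection chain for one contrast; None when nothing survives."""
    sel, log = select_instruments(exposure, ld, cfg)
    if len(sel) == 0:
        log["reason"] = "no variants pass the p-value/clumping filters"
        return None, log
    try:
        h = harmonize(sel, outcome)
    except ValueError as exc:
        log["reason"] = str(exc)
        return None, log
    log["after_harmonize"] = len(h)
    # F-filter on the harmonized exposure effects
    f = (h.beta_exp / h.se_exp) ** 2
    keep = f >= cfg.min_f
    h = h.subset(keep)
    log["after_f_filter"] = len(h)
    if len(h) == 0:
        log["reason"] = "no instruments with F above the minimum"
        return None, log
    return h, log


def _contrast_rows(
    h: HarmonizedSet, cfg: AnalysisConfig, or_scale: bool
) -> list[dict]:
    """Estimator + diagnostic rows for one harmonized contrast."""
    n = len(h)
    rows: list[dict] = []
    het = cochran_q(h) if n >= 2 else None
    q_str = _fmt(het.q) if het else "NA"
    ph_str = _fmt_p(het.pvalue) if het else "NA"
    egg_int = None

    def add(method: str, est: MrEstimate | None, pp: str = "NA") -> None:
        rows.append(
            dict(
                exposure=h.exposure_name, outcome=h.outcome_name, n_snp=n,
                method=method,
                estimate=format_estimate(est, or_scale) if est else "NA",
                pvalue=_fmt_p(est.pvalue) if est else "NA",
                Q=q_str, P_h=ph_str, P_p=pp,
            )
        )

    if "ivw" in cfg.estimators:
        add("IVW", ivw(h) if n >= 2 else None)
    if "egger" in cfg.estimators:
        if n >= 3:
            est, egg_int = egger(h)
            add("MR Egger", est, pp=_fmt_p(egg_int.pvalue))
        else:
            add("MR Egger", None)
    if "weighted_median" in cfg.estimators:
        add("Weighted median",
            weighted_median(h, n_boot=cfg.wm_n_boot, seed=cfg.seed) if n >= 3 else None)
    if "raps" in cfg.estimators:
        add("RAPS", raps(h) if n >= 3 else None)

    pr = presso(h, n_sim=cfg.presso_n_sim, sig=cfg.presso_sig, seed=cfg.seed) \
        if n >= 4 else None
    if pr is not None and pr.applicable and pr.corrected is not None:
        add("MR PRESSO", pr.corrected)
        rows[-1]["P_p"] = "NA"
    else:
        # no outliers (or too few variants): PRESSO prints NA
        add("MR PRESSO", None)
    return rows


def univariable_report(
    exposure: GwasTable,
    outcome: GwasTable,
    ld: LdMatrix | None,
    cfg: AnalysisConfig,
    or_scale: bool | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One contrast's report block (DataFrame) and its selection log."""
    if exposure.trait_name == outcome.trait_name:
        raise ValueError("exposure and outcome are the same trait")
    if or_scale is None:
        or_scale = outcome.trait_type == "binary"
    h, log = harmonized_instruments(exposure, outcome, ld, cfg)
    if h is None:
        row = dict(
            exposure=exposure.trait_name, outcome=outcome.trait_name,
            n_snp=0, method="IVW", estimate="NA", pvalue="NA",
            Q="NA", P_h="NA", P_p="NA",
        )
        return pd.DataFrame([row], columns=REPORT_COLUMNS), log
    rows = _contrast_rows(h, cfg, or_scale)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS), log


def _load_tables(paths: dict[str, str], trait_type: str) -> dict[str, GwasTable]:
    out = {}
    for label, path in paths.items():
        t, _ = read_gwas_table(path, trait_name=label, trait_type=trait_type)
        out[label] = t
    return out


def run_univariable(
    cfg: AnalysisConfig,
    exposures: dict[str, GwasTable] | None = None,
    outcomes: dict[str, GwasTable] | None = None,
    ld: LdMatrix | None = None,
) -> pd.DataFrame:
    """All exposure x outcome contrasts, concatenated into one report."""
    if exposures is None:
        exposures = _load_tables(cfg.exposures, "continuous")
    if outcomes is None:
        outcomes = _load_tables(cfg.outcomes, "binary")
    if ld is None and cfg.ld_path:
        ld = LdMatrix.from_square_tsv(cfg.ld_path)
    blocks = []
    logs = {}
    for e_label, e_tab in exposures.items():
        for o_label, o_tab in outcomes.items():
            block, log = univariable_report(e_tab, o_tab, ld, cfg)
            blocks.append(block)
            logs[f"{e_label}->{o_label}"] = log
    report = pd.concat(blocks, ignore_index=True)
    _write_outputs(cfg, "univariable", report, logs)
    return report


def run_bidirectional(
    cfg: AnalysisConfig,
    exposures: dict[str, GwasTable] | None = None,
    outcomes: dict[str, GwasTable] | None = None,
    ld: LdMatrix | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward (OR-scale) and reverse (beta-scale) reports.

    Reverse instruments are re-selected from the outcome trait's GWAS at
    the same thresholds, with the original exposure as the new outcome.
    """
    if exposures is None:
        exposures = _load_tables(cfg.exposures, "continuous")
    if outcomes is None:
        outcomes = _load_tables(cfg.outcomes, "binary")
    if ld is None and cfg.ld_path:
        ld = LdMatrix.from_square_tsv(cfg.ld_path)
    fwd_blocks, rev_blocks = [], []
    logs = {}
    for e_label, e_tab in exposures.items():
        for o_label, o_tab in outcomes.items():
            fb, fl = univariable_report(e_tab, o_tab, ld, cfg, or_scale=True)
            rb, rl = univariable_report(o_tab, e_tab, ld, cfg, or_scale=False)
            fwd_blocks.append(fb)
            rev_blocks.append(rb)
            logs[f"fwd:{e_label}->{o_label}"] = fl
            logs[f"rev:{o_label}->{e_label}"] = rl
    fwd = pd.concat(fwd_blocks, ignore_index=True)
    rev = pd.concat(rev_blocks, ignore_index=True)
    _write_outputs(cfg, "forward", fwd, logs)
    _write_outputs(cfg, "reverse", rev, {})
    return fwd, rev


def build_mvmr_input(
    exposures: dict[str, GwasTable],
    outcome: GwasTable,
    ld: LdMatrix | None,
    cfg: AnalysisConfig,
) -> MvmrInput:
    """Union of per-exposure selections, re-clumped jointly, then each
    variant's associations pulled from every exposure GWAS and the outcome."""
    selected = {}
    for label, tab in exposures.items():
        sel, _ = select_instruments(tab, ld, cfg)
        selected[label] = sel
    union_ids: list[str] = []
    for sel in selected.values():
        for s in sel.df["snp"]:
            if s not in union_ids:
                union_ids.append(s)
    # joint re-clump on the union, ranking by the best p across exposures
    frames = [s.df for s in selected.values()]
    pooled = pd.concat(frames, ignore_index=True)
    pooled = pooled.loc[pooled["snp"].isin(union_ids)]
    pooled = pooled.sort_values(["snp", "pval"], kind="stable").drop_duplicates("snp")
    pooled_table = GwasTable(trait_name="union", df=pooled)
    clumped = greedy_clump(pooled_table, ld, r2_max=cfg.clump_r2,
                           window_kb=cfg.clump_kb)
    labels = list(exposures)
    # harmonize each exposure and the outcome onto the clumped union
    harmon = {lab: harmonize(clumped, exposures[lab]) for lab in labels}
    h_out = harmonize(clumped, outcome)
    keep = [s for s in h_out.snp_ids
            if all(s in set(harmon[lab].snp_ids) for lab in labels)]
    idx_out = {s: i for i, s in enumerate(h_out.snp_ids)}
    be = np.zeros((len(keep), len(labels)))
    se = np.zeros_like(be)
    for j, lab in enumerate(labels):
        idx = {s: i for i, s in enumerate(harmon[lab].snp_ids)}
        be[:, j] = [harmon[lab].beta_out[idx[s]] for s in keep]
        se[:, j] = [harmon[lab].se_out[idx[s]] for s in keep]
    bo = np.array([h_out.beta_out[idx_out[s]] for s in keep])
    so = np.array([h_out.se_out[idx_out[s]] for s in keep])
    return MvmrInput(snp_ids=keep, beta_exp=be, se_exp=se,
                     beta_out=bo, se_out=so, exposure_names=labels)


def run_mvmr(
    cfg: AnalysisConfig,
    exposures: dict[str, GwasTable] | None = None,
    outcomes: dict[str, GwasTable] | None = None,
    ld: LdMatrix | None = None,
) -> pd.DataFrame:
    """Joint direct effects of all configured exposures on each outcome."""
    if exposures is None:
        exposures = _load_tables(cfg.exposures, "continuous")
    if outcomes is None:
        outcomes = _load_tables(cfg.outcomes, "binary")
    if ld is None and cfg.ld_path:
        ld = LdMatrix.from_square_tsv(cfg.ld_path)
    rows = []
    for o_label, o_tab in outcomes.items():
        or_scale = o_tab.trait_type == "binary"
        try:
            m = build_mvmr_input(exposures, o_tab, ld, cfg)
            ests = mvmr_ivw(m)
            egger_ests, egg_int = (mvmr_egger(m) if m.n_snp >= m.k + 2
                                   else ([], None))
        except ValueError as exc:
            rows.append(dict(exposure="|".join(exposures), outcome=o_label,
                             n_snp=0, method="MVMR IVW", estimate="NA",
                             pvalue="NA", Q="NA", P_h="NA", P_p=str(exc)))
            continue
        for e in ests:
            rows.append(dict(
                exposure=e.extra["exposure"], outcome=o_label, n_snp=e.n_snp,
                method="MVMR IVW", estimate=format_estimate(e, or_scale),
                pvalue=_fmt_p(e.pvalue), Q="NA", P_h="NA", P_p="NA",
            ))
        for e in egger_ests:
            rows.append(dict(
                exposure=e.extra["exposure"], outcome=o_label, n_snp=e.n_snp,
                method="MVMR Egger", estimate=format_estimate(e, or_scale),
                pvalue=_fmt_p(e.pvalue), Q="NA", P_h="NA",
                P_p=_fmt_p(egg_int.pvalue) if egg_int else "NA",
            ))
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    _write_outputs(cfg, "mvmr", report, {})
    return report


def run_gsea(
    cfg: AnalysisConfig,
    expression: ExpressionMatrix | None = None,
    gene_sets: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """moderated t -> ranking -> permutation GSEA -> significance filter."""
    if expression is None:
        expression = ExpressionMatrix.from_tsv(cfg.gsea_expression, cfg.gsea_groups)
    if gene_sets is None:
        gene_sets = read_gmt(cfg.gsea_gmt)
    stats_df = moderated_t(expression)
    ranked = rank_genes(stats_df)
    results = gsea_permutation(
        ranked, gene_sets, n_perm=cfg.gsea_n_perm, seed=cfg.seed,
        min_size=cfg.gsea_min_size, max_size=cfg.gsea_max_size,
    )
    sig = filter_significant(results)
    df = pd.DataFrame(
        [dict(set=r.set_name, size=r.size, es=r.es, nes=r.nes,
              pvalue=r.pvalue, qvalue=r.qvalue,
              significant=r in sig) for r in results]
    )
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if len(df):
        df.to_csv(out / "gsea_results.tsv", sep="\t", index=False)
    for name in cfg.gsea_export_sets:
        if name in gene_sets:
            _, running = enrichment_score(ranked, gene_sets[name])
            pd.DataFrame({"rank": np.arange(1, len(ranked) + 1),
                          "gene": ranked.gene_ids,
                          "running_sum": running}).to_csv(
                out / f"gsea_running_{name}.tsv", sep="\t", index=False)
    return df


def _write_outputs(cfg: AnalysisConfig, tag: str, report: pd.DataFrame,
                   logs: dict) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / f"report_{tag}.tsv", sep="\t", index=False)
    manifest = {"tag": tag, "config": {k: v for k, v in asdict(cfg).items()},
                "selection_logs": logs}
    (out / f"manifest_{tag}.json").write_text(json.dumps(manifest, indent=2,
                                                         default=str))
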
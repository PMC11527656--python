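"""Gene-set enrichment over a ranked gene list, with a moderated-t ranking.

The differential statistic is an empirical-Bayes moderated t: per-gene
pooled variances are shrunk toward a common prior whose degrees of
freedom d0 and scale s0^2 are fitted by method of moments on the log
sample variances — the standard small-sample stabilization for designs
like 3 cases vs 3 controls.  Genes are ranked by the signed statistic and
scored with the weighted Kolmogorov-Smirnov running sum: set members
("hits") push the sum up in proportion to |stat|^p, non-members pull it
down by 1/(N - N_hit); the enrichment score (ES) is the signed maximal
deviation.  Significance uses a gene-label permutation null (with 3
samples per group only 20 relabelings exist — far too few for small
p-values), normalized ES against the same-sign permutation mean, and FDR
q-values by the pooled-NES tail-ratio procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats


@dataclass
class ExpressionMatrix:
    """Log-scale genes x samples expression with case/control labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: list[str]  # per-sample: "case" | "control"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g, s = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (g, s):
            raise ValueError("values shape must be (genes, samples)")
        if len(self.groups) != s:
            raise ValueError("one group label per sample required")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene ids must be unique")
        for lab in ("case", "control"):
            if sum(x == lab for x in self.groups) < 2:
                raise ValueError(f"need >= 2 '{lab}' samples")
        if np.isnan(self.values).any():
            raise ValueError("missing values must be imputed upstream")

    def to_tsv(self, path: str | Path, groups_path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids).to_csv(
            path, sep="\t", index_label="gene", float_format="%.4f"
        )
        pd.DataFrame({"sample": self.sample_ids, "group": self.groups}).to_csv(
            groups_path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, groups_path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        gr = pd.read_csv(groups_path, sep="\t").set_index("sample")["group"]
        return cls(
            gene_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            groups=[gr[s] for s in df.columns],
        )


@dataclass
class RankedList:
    """Genes in descending order of the ranking statistic."""

    gene_ids: list[str]
    stats: np.ndarray

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GeneSetResult:
    set_name: str
    es: float
    nes: float
    pvalue: float
    qvalue: float
    size: int


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (limma-style)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderated_t(
    x: ExpressionMatrix, var_floor: float = 1e-8
) -> pd.DataFrame:
    """Per-gene log2 fold change and empirical-Bayes moderated t.

    Returns a DataFrame indexed by gene with columns log2fc, t, pvalue,
    s2 (pooled variance), s2_post (moderated), plus fitted d0 and s0^2 in
    ``df.attrs``.  Zero-variance genes are floored at ``var_floor`` and
    flagged in ``df.attrs["flagged_zero_variance"]``.
    """
    case = np.array([g == "case" for g in x.groups])
    ctrl = ~case
    n1, n2 = int(case.sum()), int(ctrl.sum())
    d = n1 + n2 - 2
    m1 = x.values[:, case].mean(axis=1)
    m2 = x.values[:, ctrl].mean(axis=1)
    log2fc = m1 - m2
    v1 = x.values[:, case].var(axis=1, ddof=1)
    v2 = x.values[:, ctrl].var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    flagged = [g for g, v in zip(x.gene_ids, s2) if v < var_floor]
    s2 = np.maximum(s2, var_floor)

    # method of moments on z = log s2:
    #   var(z) = trigamma(d/2) + trigamma(d0/2);  mean locates s0^2
    z = np.log(s2)
    var_z = float(np.var(z, ddof=1))
    if var_z < 1e-12:
        # exactly exchangeable variances carry no scatter to fit the
        # prior from: shrink each gene to itself (ordinary t recovered)
        out = pd.DataFrame(
            {
                "log2fc": log2fc,
                "t": log2fc / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2)),
                "pvalue": 2 * stats.t.sf(
                    np.abs(log2fc / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))), d),
                "s2": s2,
                "s2_post": s2,
            },
            index=pd.Index(x.gene_ids, name="gene"),
        )
        out.attrs.update(d0=np.inf, s02=float(np.exp(np.mean(z))), df_resid=d,
                         flagged_zero_variance=flagged)
        return out
    excess = var_z - float(special.polygamma(1, d / 2))
    if excess > 1e-10:
        d0 = 2.0 * _trigamma_inverse(excess)
        mean_shift = (
            special.digamma(d / 2) - np.log(d / 2)
            - (special.digamma(d0 / 2) - np.log(d0 / 2))
        )
        s02 = float(np.exp(np.mean(z) - mean_shift))
        df_total = d0 + d
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
    else:  # variances are exchangeable: complete shrinkage
        d0 = np.inf
        s02 = float(np.exp(np.mean(z) - (special.digamma(d / 2) - np.log(d / 2))))
        df_total = np.inf
        s2_post = np.full_like(s2, s02)

    t = log2fc / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {"log2fc": log2fc, "t": t, "pvalue": p, "s2": s2, "s2_post": s2_post},
        index=pd.Index(x.gene_ids, name="gene"),
    )
    out.attrs.update(d0=float(d0), s02=s02, df_resid=d,
                     flagged_zero_variance=flagged)
    return out


def rank_genes(stats_df: pd.DataFrame, metric: str = "signed_t") -> RankedList:
    """Order genes by the chosen statistic descending; ties by gene id."""
    col = {"signed_t": "t", "log2fc": "log2fc"}.get(metric)
    if col is None:
        raise ValueError(f"unknown metric {metric!r}")
    vals = stats_df[col]
    if not np.isfinite(vals).all():
        raise ValueError("ranking statistics must be finite")
    tmp = stats_df.reset_index().sort_values(
        [col, "gene"], ascending=[False, True], kind="stable"
    )
    return RankedList(gene_ids=list(tmp["gene"].astype(str)),
                      stats=tmp[col].to_numpy(dtype=float))


def enrichment_score(
    r: RankedList, gene_set: set[str] | list[str], weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running sum.

    Hits increment the sum by |stat|^p normalized over hit genes; misses
    decrement by 1/(N - N_hit).  The ES is the running-sum value of
    maximal absolute deviation (signed).
    """
    gene_set = set(gene_set)
    hit = np.array([g in gene_set for g in r.gene_ids])
    n = len(r)
    nh = int(hit.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must intersect the list strictly")
    wt = np.abs(r.stats) ** weight_p
    denom = wt[hit].sum()
    if denom == 0:  # all hit stats zero: fall back to unweighted hits
        incr = np.where(hit, 1.0 / nh, 0.0)
    else:
        incr = np.where(hit, wt / denom, 0.0)
    step = incr - np.where(hit, 0.0, 1.0 / (n - nh))
    running = np.cumsum(step)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def _es_from_positions(pos: np.ndarray, wt: np.ndarray, n: int) -> np.ndarray:
    """Batch ES from sorted hit positions (n_perm, k); wt aligned to rank."""
    n_perm, k = pos.shape
    dec = 1.0 / (n - k)
    w = wt[pos]
    wsum = w.sum(axis=1, keepdims=True)
    cw = np.cumsum(w, axis=1) / np.where(wsum > 0, wsum, 1.0)
    degenerate = wsum.squeeze(1) == 0  # all-zero stats: unweighted fallback
    if degenerate.any():
        cw[degenerate] = np.arange(1, k + 1) / k
    j = np.arange(k)[None, :]
    after = cw - dec * (pos - j)
    before = after - np.diff(np.concatenate([np.zeros((n_perm, 1)), cw], axis=1), axis=1)
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then gene ids, tab-separated."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> Path:
    with open(path, "wt") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")
    return Path(path)


def gsea_permutation(
    r: RankedList,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int | None = None,
    min_size: int = 10,
    max_size: int = 500,
    weight_p: float = 1.0,
) -> list[GeneSetResult]:
    """Permutation-based enrichment over a gene-set collection.

    The null permutes gene labels: each replicate scores a uniformly
    random set of the same size.  p is one-sided on the observed ES's
    sign with the add-one rule; NES divides by the mean same-sign
    permuted ES magnitude; q comes from the pooled tail-ratio over all
    sets' permuted NES values.  Sets outside [min_size, max_size] after
    intersection are skipped.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    n = len(r)
    genes = np.array(r.gene_ids)
    in_list = set(r.gene_ids)
    wt = np.abs(r.stats) ** weight_p

    kept: list[tuple[str, int, float]] = []
    for name in sorted(sets):  # order-independent results
        members = [g for g in set(sets[name]) if g in in_list]
        size = len(members)
        if size < min_size or size > max_size or size == n:
            continue
        es, _ = enrichment_score(r, members, weight_p=weight_p)
        kept.append((name, size, es))
    if not kept:
        return []

    # permutation null, cached per distinct set size
    null_by_size: dict[int, np.ndarray] = {}
    for _, size, _ in kept:
        if size in null_by_size:
            continue
        u = rng.random((n_perm, n))
        pos = np.sort(np.argpartition(u, size - 1, axis=1)[:, :size], axis=1)
        null_by_size[size] = _es_from_positions(pos, wt, n)

    results: list[GeneSetResult] = []
    pooled_nes: list[np.ndarray] = []
    obs_nes: list[float] = []
    for name, size, es in kept:
        null = null_by_size[size]
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        # one-sided p within the same-sign side of the null (the classic
        # convention: normalizing by all permutations would double the
        # type-I rate, since both tails could go below the level)
        if es >= 0:
            same = null[null >= 0]
            p = (1 + np.sum(same >= es)) / (1 + same.size)
            nes = es / pos_mean if np.isfinite(pos_mean) else np.nan
        else:
            same = null[null < 0]
            p = (1 + np.sum(same <= es)) / (1 + same.size)
            nes = -abs(es) / neg_mean if np.isfinite(neg_mean) else np.nan
        if not np.isfinite(nes):  # degenerate one-sided null
            nes = 0.0
        null_nes = np.where(null >= 0,
                            null / (pos_mean if np.isfinite(pos_mean) else 1.0),
                            null / (neg_mean if np.isfinite(neg_mean) else 1.0))
        pooled_nes.append(null_nes)
        obs_nes.append(float(nes))
        results.append(GeneSetResult(name, float(es), float(nes), float(p),
                                     qvalue=np.nan, size=size))

    pool = np.concatenate(pooled_nes)
    obs = np.array(obs_nes)
    for res, nes in zip(results, obs):
        if nes >= 0:
            num_pool = np.sum(pool >= nes) / max(np.sum(pool >= 0), 1)
            num_obs = np.sum(obs >= nes) / max(np.sum(obs >= 0), 1)
        else:
            num_pool = np.sum(pool <= nes) / max(np.sum(pool < 0), 1)
            num_obs = np.sum(obs <= nes) / max(np.sum(obs < 0), 1)
        res.qvalue = float(min(1.0, num_pool / num_obs)) if num_obs > 0 else 1.0
    return results


def filter_significant(
    results: list[GeneSetResult], p_max: float = 0.05, q_max: float = 0.25
) -> list[GeneSetResult]:
    """Keep sets with p < p_max AND q < q_max (strict inequalities)."""
    return [r for r in results if r.pvalue < p_max and r.qvalue < q_max]
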
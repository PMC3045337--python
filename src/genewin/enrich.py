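"""Per-window enrichment of suggestive association signal.

For each 10 kb distance window (and the exon stratum) the statistic is
the proportion of SNPs with p < alpha among all polymorphic SNPs in the
window.  The same proportion is computed for every phenotype
permutation, and the nearest-rank 2.5%/97.5% quantiles of the permuted
counts form a 95% confidence interval for the no-association
expectation; an observed count strictly above the upper bound flags the
window as significantly enriched.  Observed proportions are additionally
smoothed with a 50 kb (5-bin) sliding window for display; the exon
stratum is never smoothed.  The per-gene view counts a gene once per
stratum if any of its assigned SNPs is suggestive.

Window keys: integers -K..K (0 = inside the transcript) plus the string
``"exon"``; the exon stratum is a subset of window 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EXON = "exon"
DEFAULT_ALPHAS = (0.1, 0.01, 0.001)


@dataclass(frozen=True)
class EnrichConfig:
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    ci_level: float = 0.95
    smooth_span_bp: int = 50_000
    combine: bool = False

    def __post_init__(self) -> None:
        for a in self.alphas:
            if not 0.0 < a < 1.0:
                raise ValueError(f"alpha must be in (0, 1), got {a}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")


def window_keys(k_max: int = 10) -> list[object]:
    """Ordered window keys: -K..K then the exon stratum."""
    return list(range(-k_max, k_max + 1)) + [EXON]


def _membership(assignments: pd.DataFrame, snp_order: Sequence[str],
                k_max: int = 10) -> tuple[list[object], np.ndarray]:
    """Boolean window-membership matrix (n_windows, n_snps).

    Window 0 contains *all* transcript SNPs; the exon row repeats the
    exonic subset, so the two strata are reported separately while exon
    remains a subset of the gene window.
    """
    keys = window_keys(k_max)
    col = {sid: j for j, sid in enumerate(snp_order)}
    m = np.zeros((len(keys), len(snp_order)), dtype=bool)
    row = {k: i for i, k in enumerate(keys)}
    for sid, widx, in_exon in zip(assignments["snp_id"], assignments["window_index"],
                                  assignments["in_exon"]):
        j = col.get(sid)
        if j is None or abs(int(widx)) > k_max:
            continue
        m[row[int(widx)], j] = True
        if in_exon:
            m[row[EXON], j] = True
    return keys, m


def window_counts(assignments: pd.DataFrame, pvalues: Mapping[str, float] | pd.Series,
                  alphas: Sequence[float] = DEFAULT_ALPHAS, k_max: int = 10
                  ) -> pd.DataFrame:
    """Observed totals and suggestive counts per window and threshold.

    ``pvalues`` maps snp_id -> association p-value; a SNP with p exactly
    equal to alpha is not counted (strict inequality).  Returns a frame
    indexed by window key with columns ``n_total`` and ``n_below_<alpha>``.
    """
    for a in alphas:
        if not 0.0 < a < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {a}")
    pv = pd.Series(pvalues)
    snp_order = list(pv.index)
    keys, m = _membership(assignments, snp_order, k_max)
    p = pv.to_numpy(dtype=float)
    out = pd.DataFrame(index=pd.Index(keys, name="window"))
    out["n_total"] = m.sum(axis=1)
    for a in alphas:
        out[f"n_below_{a:g}"] = (m & (p < a)[None, :]).sum(axis=1)
    return out


def permutation_window_counts(assignments: pd.DataFrame, snp_order: Sequence[str],
                              perm_pvalues: Iterable[np.ndarray] | np.ndarray,
                              alphas: Sequence[float] = DEFAULT_ALPHAS, k_max: int = 10
                              ) -> dict[float, np.ndarray]:
    """Suggestive-SNP counts per window for every permutation.

    ``perm_pvalues`` is either the full (n_perm, n_snps) matrix or an
    iterator of row chunks (the streaming contract: only per-window
    counts are ever held, never all p-values).  Returns, per alpha, an
    array of shape (n_perm, n_windows) aligned to :func:`window_keys`.
    """
    keys, m = _membership(assignments, snp_order, k_max)
    mt = m.T.astype(np.float32)
    if isinstance(perm_pvalues, np.ndarray):
        perm_pvalues = [perm_pvalues]
    parts: dict[float, list[np.ndarray]] = {a: [] for a in alphas}
    for chunk in perm_pvalues:
        for a in alphas:
            below = (chunk < a).astype(np.float32)
            parts[a].append(np.rint(below @ mt).astype(np.int64))
    return {a: np.concatenate(parts[a], axis=0) for a in alphas}


def nearest_rank_ci(samples: np.ndarray, ci_level: float = 0.95
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-rank empirical quantile interval along axis 0.

    The bound at probability q is the value at rank ceil(q*N) (1-based)
    of the sorted sample, so bounds are always attainable values (integer
    counts stay integers).
    """
    samples = np.sort(np.asarray(samples), axis=0)
    n = samples.shape[0]
    if n < 2:
        raise ValueError("need at least 2 permutations for a CI")
    q_low = (1.0 - ci_level) / 2.0
    q_high = 1.0 - q_low
    lo_rank = max(1, math.ceil(q_low * n))
    hi_rank = min(n, math.ceil(q_high * n))
    return samples[lo_rank - 1], samples[hi_rank - 1]


def smooth_profile(values: Sequence[float], smooth_span_bp: int = 50_000,
                   window_width_bp: int = 10_000) -> np.ndarray:
    """Centred moving average over contiguous distance bins.

    The span must be an odd multiple of the bin width (50 kb / 10 kb = 5
    bins by default); at the profile edges the average runs over the bins
    actually available.
    """
    if smooth_span_bp % window_width_bp != 0 or (smooth_span_bp // window_width_bp) % 2 == 0:
        k = smooth_span_bp // window_width_bp
        k_odd = k + 1 if k % 2 == 0 else max(1, k)
        raise ValueError(
            f"smoothing span must be an odd multiple of the {window_width_bp} bp bin "
            f"width; nearest valid span is {k_odd * window_width_bp} bp")
    half = (smooth_span_bp // window_width_bp) // 2
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    for i in range(v.size):
        lo, hi = max(0, i - half), min(v.size, i + half + 1)
        out[i] = v[lo:hi].mean()
    return out


def build_enrichment_table(observed: pd.DataFrame,
                           perm_counts: Mapping[float, np.ndarray],
                           config: EnrichConfig = EnrichConfig(),
                           k_max: int = 10) -> pd.DataFrame:
    """Assemble the per-window enrichment table.

    Long format, one row per (window, alpha): totals, observed count,
    proportion, nearest-rank CI bounds on the permuted counts (and as
    proportions), the smoothed observed proportion (NaN for the exon
    stratum), and the one-sided significance flags.
    """
    keys = window_keys(k_max)
    rows = []
    smoothed_by_alpha = {}
    for a in config.alphas:
        col = f"n_below_{a:g}"
        props = []
        for w in range(-k_max, k_max + 1):
            tot = observed.loc[w, "n_total"]
            props.append(observed.loc[w, col] / tot if tot > 0 else 0.0)
        smoothed_by_alpha[a] = smooth_profile(props, config.smooth_span_bp)
    for a in config.alphas:
        lo, hi = nearest_rank_ci(perm_counts[a], config.ci_level)
        col = f"n_below_{a:g}"
        for i, w in enumerate(keys):
            n_total = int(observed.loc[w, "n_total"])
            n_below = int(observed.loc[w, col])
            prop = n_below / n_total if n_total > 0 else float("nan")
            smoothed = (float(smoothed_by_alpha[a][keys.index(w)])
                        if w != EXON else float("nan"))
            rows.append({
                "window": w, "alpha": a, "n_total": n_total, "n_below": n_below,
                "proportion": prop,
                "ci_low": int(lo[i]), "ci_high": int(hi[i]),
                "ci_low_prop": lo[i] / n_total if n_total > 0 else float("nan"),
                "ci_high_prop": hi[i] / n_total if n_total > 0 else float("nan"),
                "smoothed": smoothed,
                "significant": n_below > hi[i],
                "depleted": n_below < lo[i],
            })
    return pd.DataFrame(rows)


def count_suggestive_genes(assignments: pd.DataFrame,
                           pvalues: Mapping[str, float] | pd.Series,
                           perm_pvalues: Iterable[np.ndarray] | np.ndarray,
                           alphas: Sequence[float] = DEFAULT_ALPHAS,
                           ci_level: float = 0.95, k_max: int = 10) -> pd.DataFrame:
    """Genes with at least one suggestive SNP, per stratum and threshold.

    Strata: ``gene_100kb`` (any SNP assigned within +/-K windows,
    including the transcript) and ``exon`` (exonic SNPs only).  A gene
    counts once however many of its SNPs are suggestive.  CIs come from
    applying the identical count to each permutation.
    """
    pv = pd.Series(pvalues)
    snp_order = list(pv.index)
    col = {sid: j for j, sid in enumerate(snp_order)}
    strata = {
        "gene_100kb": assignments[assignments["window_index"].abs() <= k_max],
        "exon": assignments[assignments["in_exon"]],
    }
    if isinstance(perm_pvalues, np.ndarray):
        perm_pvalues = [perm_pvalues]
    # gene membership matrices per stratum: (n_genes, n_snps)
    mats = {}
    for name, sub in strata.items():
        genes = sorted(sub["gene_id"].unique())
        g_row = {g: i for i, g in enumerate(genes)}
        m = np.zeros((len(genes), len(snp_order)), dtype=bool)
        for sid, gid in zip(sub["snp_id"], sub["gene_id"]):
            j = col.get(sid)
            if j is not None:
                m[g_row[gid], j] = True
        mats[name] = m
    obs_p = pv.to_numpy(dtype=float)
    perm_gene_counts: dict[tuple[str, float], list[np.ndarray]] = {
        (n, a): [] for n in strata for a in alphas}
    for chunk in perm_pvalues:
        for a in alphas:
            below = (chunk < a).astype(np.float32)
            for name, m in mats.items():
                hits = below @ m.T.astype(np.float32)  # (chunk, n_genes)
                perm_gene_counts[(name, a)].append((hits > 0.5).sum(axis=1))
    rows = []
    for name, m in mats.items():
        total = int(m.any(axis=1).sum())
        for a in alphas:
            observed = int(((m & (obs_p < a)[None, :]).any(axis=1)).sum())
            counts = np.concatenate(perm_gene_counts[(name, a)])
            lo, hi = nearest_rank_ci(counts[:, None], ci_level)
            rows.append({
                "stratum": name, "alpha": a, "total_genes": total,
                "observed": observed, "ci_low": int(lo[0]), "ci_high": int(hi[0]),
                "significant": observed > hi[0],
            })
    return pd.DataFrame(rows)


def combine_traits(observed_list: Sequence[pd.DataFrame],
                   perm_counts_list: Sequence[Mapping[float, np.ndarray]],
                   config: EnrichConfig = EnrichConfig(),
                   k_max: int = 10) -> pd.DataFrame:
    """Combine several traits by averaging counts window-by-window.

    Observed suggestive counts and totals are averaged across traits, and
    the permuted counts are averaged permutation-by-permutation (the r-th
    combined permutation is the mean of each trait's r-th permutation),
    after which the CI is taken as usual.  All traits must share the
    window structure and permutation count.
    """
    if not observed_list:
        raise ValueError("no traits to combine")
    base_index = observed_list[0].index
    for obs in observed_list[1:]:
        if not obs.index.equals(base_index):
            raise ValueError("window structures differ between traits")
    mean_obs = sum(o.astype(float) for o in observed_list) / len(observed_list)
    combined_perm = {}
    for a in config.alphas:
        shapes = {pc[a].shape for pc in perm_counts_list}
        if len(shapes) != 1:
            raise ValueError("permutation count/window shape differs between traits")
        combined_perm[a] = sum(pc[a].astype(float) for pc in perm_counts_list) / len(perm_counts_list)
    keys = window_keys(k_max)
    rows = []
    smoothed_by_alpha = {}
    for a in config.alphas:
        col = f"n_below_{a:g}"
        props = [mean_obs.loc[w, col] / mean_obs.loc[w, "n_total"]
                 if mean_obs.loc[w, "n_total"] > 0 else 0.0
                 for w in range(-k_max, k_max + 1)]
        smoothed_by_alpha[a] = smooth_profile(props, config.smooth_span_bp)
    for a in config.alphas:
        lo, hi = nearest_rank_ci(combined_perm[a], config.ci_level)
        col = f"n_below_{a:g}"
        for i, w in enumerate(keys):
            n_total = float(mean_obs.loc[w, "n_total"])
            n_below = float(mean_obs.loc[w, col])
            rows.append({
                "window": w, "alpha": a, "n_total": n_total, "n_below": n_below,
                "proportion": n_below / n_total if n_total > 0 else float("nan"),
                "ci_low": float(lo[i]), "ci_high": float(hi[i]),
                "ci_low_prop": lo[i] / n_total if n_total > 0 else float("nan"),
                "ci_high_prop": hi[i] / n_total if n_total > 0 else float("nan"),
                "smoothed": (float(smoothed_by_alpha[a][keys.index(w)])
                             if w != EXON else float("nan")),
                "significant": n_below > hi[i],
                "depleted": n_below < lo[i],
            })
    return pd.DataFrame(rows)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for c in ("significant", "depleted"):
        if c in df.columns:
            df[c] = df[c].astype(bool)
    return df
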
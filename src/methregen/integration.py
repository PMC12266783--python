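"""Methylome-transcriptome integration via TSS-distance regulatory potential.

Significant DM CpGs become single-bp "methylation peaks". Each gene is
scored by a regulatory potential that sums exponentially decaying peak
contributions with distance from the strand-aware TSS:

    RP(g) = sum over peaks with |pos - tss| <= D of
            exp(-(alpha + beta * |pos - tss| / D))

with defaults alpha = 0.5, beta = 4, D = 100 kb. Genes in each
differential-expression direction set are ranked by RP (descending) and
by DE p-value (ascending); the rank product (r_RP * r_DE) / n^2 orders
candidate epigenetically regulated targets. Whether peaks act as
activators (up-regulated set) or repressors (down-regulated set) is
tested by a one-sided two-sample comparison of RP empirical CDFs against
a non-differential background, asymptotically or by label permutation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneModel, MethylationPeak, ValidationError

log = logging.getLogger("methregen.integration")

__all__ = [
    "RegulatoryPotentialParams",
    "DirectionTestResult",
    "peaks_from_dm",
    "regulatory_potential",
    "score_genes",
    "rank_product_integration",
    "direction_test",
    "overlap_sets",
]


@dataclass(frozen=True)
class RegulatoryPotentialParams:
    """Decay constants of the regulatory-potential kernel."""

    alpha: float = 0.5
    beta_decay: float = 4.0
    window_d: int = 100_000

    def __post_init__(self):
        if not (self.window_d > 0 and self.beta_decay > 0):
            raise ValidationError("require window_d > 0 and beta_decay > 0")


def peaks_from_dm(
    dm: pd.DataFrame,
    manifest: pd.DataFrame | None = None,
    q_threshold: float = 0.05,
    direction_filter: str = "both",
) -> list[MethylationPeak]:
    """Single-bp peaks from significant DM records, sorted by (chrom, pos).

    ``dm`` must carry probe_id/effect/q (and chrom/pos unless a manifest
    supplies them). ``direction_filter`` is one of both/hypo_only/hyper_only.
    """
    if direction_filter not in ("both", "hypo_only", "hyper_only"):
        raise ValidationError(f"bad direction_filter {direction_filter!r}")
    sig = dm[(dm["q"] < q_threshold) & (dm["effect"] != 0)].copy()
    if sig.empty:
        return []
    if "chrom" not in sig.columns or "pos" not in sig.columns or sig["pos"].isna().any():
        if manifest is None:
            raise ValidationError("peaks need probe positions: supply a manifest")
        pos = manifest.set_index("probe_id")[["chrom", "pos"]]
        absent = [p for p in sig["probe_id"] if p not in pos.index]
        if absent:
            raise ValidationError(f"significant probes absent from manifest: {absent[:10]}")
        sig = sig.drop(columns=["chrom", "pos"], errors="ignore").join(pos, on="probe_id")
    direction = np.where(sig["effect"] < 0, "hypo", "hyper")
    if direction_filter == "hypo_only":
        keep = direction == "hypo"
    elif direction_filter == "hyper_only":
        keep = direction == "hyper"
    else:
        keep = np.ones(len(sig), dtype=bool)
    peaks = [
        MethylationPeak(chrom=str(c), pos=int(p), probe_id=str(pid), direction=str(d))
        for c, p, pid, d in zip(
            sig["chrom"][keep], sig["pos"][keep], sig["probe_id"][keep], direction[keep]
        )
    ]
    return sorted(peaks, key=lambda pk: (pk.chrom, pk.pos, pk.probe_id))


def regulatory_potential(
    gene: GeneModel,
    peaks,
    params: RegulatoryPotentialParams = RegulatoryPotentialParams(),
) -> float:
    """Regulatory potential of one gene (strand-agnostic absolute TSS distance)."""
    d = np.array(
        [abs(pk.pos - gene.tss) for pk in peaks if pk.chrom == gene.chrom], dtype=float
    )
    d = d[d <= params.window_d]
    if d.size == 0:
        return 0.0
    return float(np.exp(-(params.alpha + params.beta_decay * d / params.window_d)).sum())


def score_genes(
    genes,
    peaks,
    params: RegulatoryPotentialParams = RegulatoryPotentialParams(),
) -> pd.DataFrame:
    """Vectorized RP and in-window peak count for every gene."""
    by_chrom: dict[str, np.ndarray] = {}
    for pk in peaks:
        by_chrom.setdefault(pk.chrom, []).append(pk.pos)
    by_chrom = {c: np.sort(np.asarray(v, dtype=float)) for c, v in by_chrom.items()}
    rows = []
    for g in genes:
        pos = by_chrom.get(g.chrom)
        if pos is None or pos.size == 0:
            rows.append((g.gene_id, 0.0, 0))
            continue
        lo = np.searchsorted(pos, g.tss - params.window_d, side="left")
        hi = np.searchsorted(pos, g.tss + params.window_d, side="right")
        d = np.abs(pos[lo:hi] - g.tss)
        rp = float(np.exp(-(params.alpha + params.beta_decay * d / params.window_d)).sum())
        rows.append((g.gene_id, rp, int(d.size)))
    return pd.DataFrame(rows, columns=["gene_id", "rp", "n_peaks"]).set_index("gene_id")


def _ordinal_ranks(keys: pd.DataFrame) -> np.ndarray:
    """1-based ranks after a deterministic lexicographic sort of ``keys``."""
    order = np.lexsort([keys[c].to_numpy() for c in reversed(keys.columns)])
    ranks = np.empty(len(keys), dtype=int)
    ranks[order] = np.arange(1, len(keys) + 1)
    return ranks


def rank_product_integration(
    rp_scores: pd.DataFrame,
    de: pd.DataFrame,
    de_adj_p_threshold: float = 0.05,
    rank_product_cutoff: float = 0.25,
) -> pd.DataFrame:
    """Rank-product target prediction within each DE direction set.

    Genes with DE adj_p < threshold split into up (lfc > 0) and down
    (lfc < 0) sets. Within a set, rank_rp orders genes by RP descending
    and rank_de by DE p ascending (ties broken by gene_id); the rank
    product is (rank_rp * rank_de) / n^2. A gene is a predicted target
    when its rank product is at or below the cutoff and it has >= 1 peak.
    """
    de = de.set_index("gene_id") if "gene_id" in de.columns else de
    common = [g for g in de.index if g in rp_scores.index]
    de = de.loc[common]
    frames = []
    for label, mask in (
        ("up", (de["adj_p"] < de_adj_p_threshold) & (de["log2_fold_change"] > 0)),
        ("down", (de["adj_p"] < de_adj_p_threshold) & (de["log2_fold_change"] < 0)),
    ):
        sub = de[mask]
        if sub.empty:
            log.info("empty DE direction set %s", label)
            continue
        n = len(sub)
        rp = rp_scores.loc[sub.index, "rp"].to_numpy(dtype=float)
        n_peaks = rp_scores.loc[sub.index, "n_peaks"].to_numpy(dtype=int)
        keys_rp = pd.DataFrame({"neg_rp": -rp, "gene_id": sub.index})
        keys_de = pd.DataFrame({"p": sub["p"].to_numpy(dtype=float), "gene_id": sub.index})
        rank_rp = _ordinal_ranks(keys_rp)
        rank_de = _ordinal_ranks(keys_de)
        rank_product = rank_rp * rank_de / n**2
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": sub.index,
                    "de_class": label,
                    "rp": rp,
                    "n_peaks": n_peaks,
                    "rank_rp": rank_rp,
                    "rank_de": rank_de,
                    "rank_product": rank_product,
                    "predicted": (rank_product <= rank_product_cutoff) & (n_peaks >= 1),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "gene_id", "de_class", "rp", "n_peaks",
                "rank_rp", "rank_de", "rank_product", "predicted",
            ]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class DirectionTestResult:
    """One-sided CDF comparison of a DE set's RP against the background."""

    set_label: str
    d_plus: float
    p: float
    n_set: int
    n_background: int
    method: str

    def to_dict(self) -> dict:
        return {
            "set_label": self.set_label,
            "d_plus": self.d_plus,
            "p": self.p,
            "n_set": self.n_set,
            "n_background": self.n_background,
            "method": self.method,
        }


def _d_plus(set_values: np.ndarray, bg_values: np.ndarray) -> float:
    """sup_x [F_bg(x) - F_set(x)]: positive when the set is shifted upward."""
    grid = np.concatenate([set_values, bg_values])
    grid.sort(kind="stable")
    f_set = np.searchsorted(np.sort(set_values), grid, side="right") / set_values.size
    f_bg = np.searchsorted(np.sort(bg_values), grid, side="right") / bg_values.size
    return float(np.max(f_bg - f_set))


def direction_test(
    rp_scores: pd.DataFrame,
    de: pd.DataFrame,
    set_label: str,
    de_adj_p_threshold: float = 0.05,
    background_min_adj_p: float = 0.5,
    method: str = "auto",
    n_permutations: int = 9_999,
    seed: int | None = None,
) -> DirectionTestResult:
    """Test whether the up- (or down-) regulated set has elevated RP.

    The asymptotic one-sided two-sample KS p-value
    exp(-2 D+^2 mn/(m+n)) is used when min(m, n) >= 50 (method="auto");
    otherwise label permutation with p = (1 + #{D+_perm >= D+_obs})/(B+1).
    """
    if set_label not in ("up", "down"):
        raise ValidationError("set_label must be 'up' or 'down'")
    de = de.set_index("gene_id") if "gene_id" in de.columns else de
    common = de.index.intersection(rp_scores.index)
    de = de.loc[common]
    sign = 1 if set_label == "up" else -1
    set_genes = de.index[
        (de["adj_p"] < de_adj_p_threshold) & (sign * de["log2_fold_change"] > 0)
    ]
    bg_genes = de.index[de["adj_p"] >= background_min_adj_p]
    overlap = set_genes.intersection(bg_genes)
    if len(overlap):
        raise ValidationError(f"set and background overlap: {list(overlap[:5])}")
    if len(set_genes) == 0 or len(bg_genes) == 0:
        raise ValidationError(f"empty {'set' if not len(set_genes) else 'background'} for {set_label}")
    x = rp_scores.loc[set_genes, "rp"].to_numpy(dtype=float)
    y = rp_scores.loc[bg_genes, "rp"].to_numpy(dtype=float)
    m, n = x.size, y.size
    d_obs = _d_plus(x, y)
    if method == "auto":
        method = "asymptotic" if min(m, n) >= 50 else "permutation"
    if method == "asymptotic":
        p = math.exp(-2.0 * d_obs**2 * m * n / (m + n))
        return DirectionTestResult(set_label, d_obs, min(p, 1.0), m, n, "asymptotic")
    if method != "permutation":
        raise ValidationError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if _d_plus(perm[:m], perm[m:]) >= d_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return DirectionTestResult(
        set_label, d_obs, p, m, n, f"permutation(seed={seed},B={n_permutations})"
    )


def overlap_sets(genes_a, genes_b) -> dict:
    """Exact partition of two gene-id sets."""
    a, b = set(genes_a), set(genes_b)
    shared = a & b
    return {
        "n_a_only": len(a - b),
        "n_b_only": len(b - a),
        "n_shared": len(shared),
        "shared": sorted(shared),
    }
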
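"""Window-density tracks, subgenome comparisons, telomere-bias enrichment
with a permutation null, size-class summaries and the disease index.

Chromosomes are tiled into non-overlapping windows (1 Mb, 500 kb, or 1,000
equal windows per chromosome); an SV is assigned to the window containing
its start.  Telomeric bias is the ratio of mean density over the outer 20%
of windows (10% at each end, pooled across chromosomes) to the mean over
interior windows; its significance comes from shuffling window counts
within each chromosome.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variants import StructuralVariant

SCHEMES = ("fixed_1Mb", "fixed_500kb", "equal_1000")


@dataclass
class WindowDensityTrack:
    scheme: str
    windows: pd.DataFrame
    # columns: chrom, index, start, end, sv_count, density (per Mb), subgenome

    @property
    def total_count(self) -> int:
        return int(self.windows["sv_count"].sum())


@dataclass
class EnrichmentResult:
    observed_fold: float
    n_perm: int
    p_value: float
    seed: int
    telomere_fraction: float = 0.2
    per_chrom_fold: dict[str, float] | None = None


def _window_edges(length: int, scheme: str, n_equal: int = 1000) -> np.ndarray:
    if scheme == "fixed_1Mb":
        size = 1_000_000
    elif scheme == "fixed_500kb":
        size = 500_000
    elif scheme == "equal_1000":
        size = max(1, length // n_equal)
        edges = np.arange(0, size * n_equal, size, dtype=np.int64)
        return np.append(edges, length)  # last window absorbs the remainder
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    edges = np.arange(0, length, size, dtype=np.int64)
    return np.append(edges, length)


def window_densities(svs: list[StructuralVariant],
                     chrom_table: list[tuple[str, int, str]],
                     scheme: str = "equal_1000",
                     n_equal: int = 1000) -> WindowDensityTrack:
    """Tile chromosomes and count SVs per window (density = count per Mb).

    ``chrom_table`` rows are (chrom, length, subgenome).  SVs on unknown
    chromosomes are an error.
    """
    known = {c for c, _, _ in chrom_table}
    offenders = sorted({s.ref_chrom for s in svs} - known)
    if offenders:
        raise ValueError(f"SVs on unknown chromosomes: {', '.join(offenders)}")
    rows = []
    for chrom, length, sub in chrom_table:
        edges = _window_edges(length, scheme, n_equal)
        pos = np.array([s.ref_start for s in svs if s.ref_chrom == chrom])
        counts = (np.histogram(pos, bins=edges)[0] if pos.size
                  else np.zeros(edges.size - 1, dtype=int))
        widths_mb = np.diff(edges) / 1e6
        for i in range(edges.size - 1):
            rows.append((chrom, i, int(edges[i]), int(edges[i + 1]),
                         int(counts[i]), counts[i] / widths_mb[i], sub))
    df = pd.DataFrame(rows, columns=["chrom", "index", "start", "end",
                                     "sv_count", "density", "subgenome"])
    return WindowDensityTrack(scheme, df)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (rank-sum form, midranks for ties) and two-sided p.

    Exact enumeration when n1 + n2 <= 12 without ties; otherwise normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = ranks[:x.size].sum() - x.size * (x.size + 1) / 2
    if np.all(pooled == pooled[0]):
        return float(u1), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def subgenome_density_test(track: WindowDensityTrack) -> tuple[float, float]:
    """Compare pooled window densities between the A and D subgenomes."""
    df = track.windows
    a = df.loc[df.subgenome == "A", "density"].to_numpy()
    d = df.loc[df.subgenome == "D", "density"].to_numpy()
    return mann_whitney_u(a, d)


def _telomere_mask(n_windows: int, fraction: float) -> np.ndarray:
    k = max(1, int(round(n_windows * fraction / 2)))
    mask = np.zeros(n_windows, dtype=bool)
    mask[:k] = True
    mask[n_windows - k:] = True
    return mask


def telomere_fold(track: WindowDensityTrack,
                  telomere_fraction: float = 0.2) -> float:
    """Mean telomeric density over mean interior density, windows pooled
    across chromosomes.  Infinite when the interior has no SVs."""
    telo, inner = [], []
    for _, grp in track.windows.groupby("chrom", sort=False):
        dens = grp.sort_values("index")["density"].to_numpy()
        mask = _telomere_mask(dens.size, telomere_fraction)
        telo.append(dens[mask])
        inner.append(dens[~mask])
    telo_mean = float(np.concatenate(telo).mean())
    inner_mean = float(np.concatenate(inner).mean())
    if inner_mean == 0:
        warnings.warn("interior density is zero; fold is infinite")
        return float("inf")
    return telo_mean / inner_mean


def permutation_pvalue(track: WindowDensityTrack, n_perm: int = 10_000,
                       seed: int = 0,
                       telomere_fraction: float = 0.2) -> EnrichmentResult:
    """Permutation test of telomeric fold-enrichment.

    The null shuffles window counts across window positions within each
    chromosome (per-chromosome totals preserved);
    p = (1 + #{permuted fold >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    chrom_dens: list[np.ndarray] = []
    chrom_masks: list[np.ndarray] = []
    per_chrom_fold: dict[str, float] = {}
    for chrom, grp in track.windows.groupby("chrom", sort=False):
        dens = grp.sort_values("index")["density"].to_numpy()
        mask = _telomere_mask(dens.size, telomere_fraction)
        chrom_dens.append(dens)
        chrom_masks.append(mask)
        t = dens[mask].mean()
        i = dens[~mask].mean()
        per_chrom_fold[chrom] = float(t / i) if i > 0 else float("inf")
    telo_all = np.concatenate([d[m] for d, m in zip(chrom_dens, chrom_masks)])
    inner_all = np.concatenate([d[~m] for d, m in zip(chrom_dens, chrom_masks)])
    if inner_all.mean() == 0:
        observed = float("inf")
    else:
        observed = float(telo_all.mean() / inner_all.mean())
    n_telo = telo_all.size
    n_inner = inner_all.size
    telo_sums = np.zeros(n_perm)
    total = sum(float(d.sum()) for d in chrom_dens)
    for dens, mask in zip(chrom_dens, chrom_masks):
        # sum of densities landing in telomeric positions per permutation
        perm = rng.permuted(np.broadcast_to(dens, (n_perm, dens.size)).copy(),
                            axis=1)
        telo_sums += perm[:, mask].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        folds = (telo_sums / n_telo) / ((total - telo_sums) / n_inner)
    exceed = int(np.sum(folds >= observed)) if np.isfinite(observed) else \
        int(np.sum(np.isinf(folds)))
    p = (1 + exceed) / (1 + n_perm)
    return EnrichmentResult(observed_fold=observed, n_perm=n_perm, p_value=p,
                            seed=seed, telomere_fraction=telomere_fraction,
                            per_chrom_fold=per_chrom_fold)


def size_class_summary(svs: list[StructuralVariant],
                       bounds: tuple[int, ...] = (10, 50, 250)
                       ) -> pd.DataFrame:
    """Fractions of INS/DEL lengths per size class (<=10, 11-50, 51-250,
    >250 by default)."""
    lengths = np.array([s.length for s in svs if s.type in ("INS", "DEL")])
    edges = [0, *bounds, np.inf]
    labels = [f"<={bounds[0]}"] + \
        [f"{a + 1}-{b}" for a, b in zip(bounds[:-1], bounds[1:])] + \
        [f">{bounds[-1]}"]
    counts = np.histogram(lengths, bins=edges)[0] if lengths.size else \
        np.zeros(len(labels), dtype=int)
    frac = counts / counts.sum() if counts.sum() else np.zeros(len(labels))
    return pd.DataFrame({"size_class": labels, "count": counts,
                         "fraction": frac})


def disease_index(grade_counts) -> float:
    """Disease index on a 0-100 scale from ordinal symptom grades 0-4:
    DI = 100 x sum(g x n_g) / (4 x N)."""
    counts = np.asarray(grade_counts, dtype=float)
    if counts.size != 5 or (counts < 0).any():
        raise ValueError("grade_counts must be five non-negative counts")
    n = counts.sum()
    if n == 0:
        raise ValueError("no plants graded")
    grades = np.arange(5)
    return float(100 * (grades * counts).sum() / (4 * n))
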
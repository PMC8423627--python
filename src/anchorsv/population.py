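"""Population-scale SV merging, filtering and cohort statistics.

Per-accession SV calls are merged into a nonredundant set of loci by
single-linkage clustering of same-type calls (breakpoints within
``pos_tol``, relative length difference within ``len_tol``), each locus
represented by median breakpoints.  Loci must be supported by at least
``min_support`` accessions (default 10).  Downstream: MAF / missing-ratio /
depth filters, cohort-acquired loci (high frequency in a modern cohort but
not in an early one), overlap with donor-specific SVs in an introgression
trio, and the priority-based theoretical gene-family count.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import StructuralVariant


@dataclass
class SVCall:
    accession: str
    type: str
    chrom: str
    start: int
    end: int
    length: int
    depth: int = 0
    genotype: str = "present"   # present | absent | missing

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.genotype not in ("present", "absent", "missing"):
            raise ValueError(f"bad genotype {self.genotype!r}")


@dataclass
class SVPresenceMatrix:
    """Merged loci x accessions with states and depths.

    ``loci``: DataFrame (locus_id, type, chrom, start, end, length,
    support); ``states``/``depths``: DataFrames indexed by locus_id with
    one column per accession.  Frequencies are computed over non-missing
    accessions.
    """

    loci: pd.DataFrame
    states: pd.DataFrame
    depths: pd.DataFrame
    dropped_low_support: int = 0

    @property
    def accessions(self) -> list[str]:
        return list(self.states.columns)

    def frequency(self, accessions: list[str] | None = None) -> pd.Series:
        sub = self.states if accessions is None else self.states[accessions]
        present = (sub == "present").sum(axis=1)
        informative = (sub != "missing").sum(axis=1)
        return present / informative.replace(0, np.nan)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _compatible(a: SVCall, b: SVCall, pos_tol: int, len_tol: float) -> bool:
    if a.type != b.type or a.chrom != b.chrom:
        return False
    if abs(a.start - b.start) > pos_tol or abs(a.end - b.end) > pos_tol:
        return False
    longer = max(a.length, b.length)
    return abs(a.length - b.length) <= len_tol * longer


def merge_calls(calls: list[SVCall], pos_tol: int = 100,
                len_tol: float = 0.2, min_support: int = 10,
                accessions: list[str] | None = None) -> SVPresenceMatrix:
    """Merge per-accession calls into a nonredundant presence matrix.

    Single-linkage clustering; the merged locus takes median breakpoints
    and length.  Same-type calls only; conflicting types at identical
    coordinates stay separate loci.  Loci with fewer than ``min_support``
    present accessions are dropped (the count is reported on the result).
    Explicit ``missing`` calls mark that accession missing at the matched
    locus; accessions with no call at a locus are ``absent``.
    """
    acc_order = accessions or sorted({c.accession for c in calls})
    present = [c for c in calls if c.genotype == "present"]
    present.sort(key=lambda c: (c.type, c.chrom, c.start))
    uf = _UnionFind(len(present))
    for i, a in enumerate(present):
        for j in range(i + 1, len(present)):
            b = present[j]
            if (b.type, b.chrom) != (a.type, a.chrom) or \
                    b.start - a.start > pos_tol:
                break
            if _compatible(a, b, pos_tol, len_tol):
                uf.union(i, j)
    clusters: dict[int, list[SVCall]] = {}
    for i, c in enumerate(present):
        clusters.setdefault(uf.find(i), []).append(c)

    loci_rows, state_rows, depth_rows = [], [], []
    dropped = 0
    ordered = sorted(clusters.values(),
                     key=lambda cl: (cl[0].chrom, int(np.median([c.start for c in cl]))))
    missing_calls = [c for c in calls if c.genotype == "missing"]
    for members in ordered:
        supporters = {c.accession for c in members}
        if len(supporters) < min_support:
            dropped += 1
            continue
        start = int(np.median([c.start for c in members]))
        end = int(np.median([c.end for c in members]))
        length = int(np.median([c.length for c in members]))
        lid = f"{members[0].type}_{members[0].chrom}_{start}"
        loci_rows.append((lid, members[0].type, members[0].chrom,
                          start, end, length, len(supporters)))
        state = {a: "absent" for a in acc_order}
        depth = {a: 0 for a in acc_order}
        for c in members:
            state[c.accession] = "present"
            depth[c.accession] = max(depth[c.accession], c.depth)
        rep = SVCall("", members[0].type, members[0].chrom, start, end, length)
        for m in missing_calls:
            if _compatible(rep, SVCall(m.accession, m.type, m.chrom, m.start,
                                       m.end, max(m.length, 1)),
                           pos_tol, len_tol) and state[m.accession] == "absent":
                state[m.accession] = "missing"
        state_rows.append(state)
        depth_rows.append(depth)
    loci = pd.DataFrame(loci_rows, columns=["locus_id", "type", "chrom",
                                            "start", "end", "length",
                                            "support"]).set_index("locus_id")
    index = loci.index
    states = pd.DataFrame(state_rows, index=index, columns=acc_order,
                          dtype=object) if loci_rows else \
        pd.DataFrame(columns=acc_order, dtype=object)
    depths = pd.DataFrame(depth_rows, index=index, columns=acc_order,
                          dtype=int) if loci_rows else \
        pd.DataFrame(columns=acc_order, dtype=int)
    return SVPresenceMatrix(loci, states, depths, dropped_low_support=dropped)


def matrix_to_calls(matrix: SVPresenceMatrix) -> list[SVCall]:
    """Re-expand a presence matrix into per-accession calls (for
    idempotence checks and re-merging)."""
    out = []
    for lid, row in matrix.loci.iterrows():
        for acc in matrix.accessions:
            g = matrix.states.at[lid, acc]
            if g == "absent":
                continue
            out.append(SVCall(acc, row["type"], row["chrom"], int(row["start"]),
                              int(row["end"]), int(row["length"]),
                              int(matrix.depths.at[lid, acc]), g))
    return out


def population_filter(matrix: SVPresenceMatrix, maf: float = 0.05,
                      missing: float = 0.2, depth: int = 3
                      ) -> tuple[SVPresenceMatrix, dict]:
    """Apply MAF >= ``maf``, missing ratio <= ``missing``, depth >= ``depth``.

    Present/absent states with depth below ``depth`` become missing; loci
    failing the missing-ratio or minor-state-frequency thresholds are
    removed.  Returns the filtered matrix and retained/removed counts.
    """
    states = matrix.states.copy()
    low_depth = matrix.depths < depth
    present_mask = states == "present"
    states = states.where(~(low_depth & present_mask), "missing")
    n_acc = len(matrix.accessions)
    miss_frac = (states == "missing").sum(axis=1) / max(n_acc, 1)
    present = (states == "present").sum(axis=1)
    informative = (states != "missing").sum(axis=1)
    freq = present / informative.replace(0, np.nan)
    minor = np.minimum(freq, 1 - freq)
    keep = (miss_frac <= missing) & (minor.fillna(0) >= maf)
    kept = matrix.loci.index[keep]
    report = {"retained": int(keep.sum()), "removed": int((~keep).sum())}
    return SVPresenceMatrix(matrix.loci.loc[kept], states.loc[kept],
                            matrix.depths.loc[kept]), report


def acquired_svs(matrix: SVPresenceMatrix, cohort_early: list[str],
                 cohort_modern: list[str], freq: float = 0.51,
                 max_early_freq: float = 0.51) -> list[str]:
    """Loci acquired by the modern cohort: present in >= ``freq`` of modern
    accessions and < ``max_early_freq`` of early accessions (frequencies
    over non-missing calls)."""
    early, modern = set(cohort_early), set(cohort_modern)
    if not early or not modern:
        raise ValueError("cohorts must be non-empty")
    if early & modern:
        raise ValueError(f"cohorts overlap: {sorted(early & modern)}")
    f_mod = matrix.frequency(list(cohort_modern)).fillna(0)
    f_early = matrix.frequency(list(cohort_early)).fillna(0)
    keep = (f_mod >= freq) & (f_early < max_early_freq)
    return list(matrix.loci.index[keep])


def subgenome_summary(matrix: SVPresenceMatrix, locus_ids: list[str],
                      chrom_table: list[tuple[str, int, str]]) -> pd.DataFrame:
    """Count and density (per kb) of the given loci per subgenome."""
    sub_of = {c: s for c, _, s in chrom_table}
    kb = {}
    for c, length, s in chrom_table:
        kb[s] = kb.get(s, 0) + length / 1e3
    loci = matrix.loci.loc[locus_ids]
    counts = loci["chrom"].map(sub_of).value_counts()
    rows = [(s, int(counts.get(s, 0)), counts.get(s, 0) / kb[s])
            for s in sorted(kb)]
    return pd.DataFrame(rows, columns=["subgenome", "count", "density_per_kb"])


def _reciprocal_overlap(a: StructuralVariant, b: StructuralVariant) -> float:
    a0, a1 = a.ref_start, max(a.ref_end, a.ref_start + 1)
    b0, b1 = b.ref_start, max(b.ref_end, b.ref_start + 1)
    ov = min(a1, b1) - max(a0, b0)
    if ov <= 0:
        return 0.0
    return min(ov / (a1 - a0), ov / (b1 - b0))


def introgression_overlap(line_specific: list[StructuralVariant],
                          donor_specific: list[StructuralVariant],
                          pos_tol: int = 100,
                          min_reciprocal: float = 0.5
                          ) -> list[StructuralVariant]:
    """Line-specific SVs matching a donor-specific SV: same type and
    chromosome, reciprocal overlap >= ``min_reciprocal`` or breakpoints
    within ``pos_tol`` -> reported as transferred."""
    by_key: dict[tuple[str, str], list[StructuralVariant]] = {}
    for d in donor_specific:
        by_key.setdefault((d.type, d.ref_chrom), []).append(d)
    out = []
    for sv in line_specific:
        for d in by_key.get((sv.type, sv.ref_chrom), []):
            if _reciprocal_overlap(sv, d) >= min_reciprocal or \
                    (abs(sv.ref_start - d.ref_start) <= pos_tol and
                     abs(sv.ref_end - d.ref_end) <= pos_tol):
                out.append(sv)
                break
    return out


def priority_gene_count(table: pd.DataFrame, priority: list[str]
                        ) -> tuple[pd.DataFrame, int]:
    """Theoretical gene resource: per family, the maximum gene count over
    source genomes, attributed to the highest-priority source attaining it.

    ``table``: families x sources, non-negative counts.  Returns a
    DataFrame (family, source, count) and the total.
    """
    if table.empty:
        return pd.DataFrame(columns=["family", "source", "count"]), 0
    missing = [s for s in priority if s not in table.columns]
    if missing:
        raise ValueError(f"priority sources absent from table: {missing}")
    rows = []
    total = 0
    for family, counts in table.iterrows():
        best = counts.max()
        source = next(s for s in priority if counts[s] == best)
        rows.append((family, source, int(best)))
        total += int(best)
    return pd.DataFrame(rows, columns=["family", "source", "count"]), total


def consistency_support(pairwise_svs: list[StructuralVariant],
                        matrix: SVPresenceMatrix, pos_tol: int = 100,
                        len_tol: float = 0.2, min_support: int = 10
                        ) -> list[tuple[StructuralVariant, int]]:
    """Pairwise (assembly-vs-assembly) SVs consistent with the population:
    a matching merged locus (same type, breakpoints within ``pos_tol``,
    length within ``len_tol``) with support >= ``min_support``.  Returns
    (SV, supporting-accession count) pairs."""
    out = []
    loci = matrix.loci
    for sv in pairwise_svs:
        cand = loci[(loci["type"] == sv.type) & (loci["chrom"] == sv.ref_chrom)]
        for _, row in cand.iterrows():
            end = sv.ref_end if sv.ref_end > sv.ref_start else sv.ref_start
            if abs(row["start"] - sv.ref_start) > pos_tol:
                continue
            if abs(row["end"] - end) > pos_tol:
                continue
            longer = max(row["length"], sv.length)
            if abs(row["length"] - sv.length) > len_tol * longer:
                continue
            if row["support"] >= min_support:
                out.append((sv, int(row["support"])))
                break
    return out
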
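"""Independent brute-force reference implementations used to cross-check the
package's vectorised/optimised code paths on small instances."""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_filter_chain(variants: pd.DataFrame, n_bulks: int,
                       min_alt_mq20=3, max_other_mean=1.0, tol=0.20,
                       mask_window=100_000, mask_min=20, mask_step=None,
                       chrom_lengths=None) -> set[tuple]:
    """Plain-python re-statement of the caller's accept rule + fragment mask."""
    mask_step = mask_step or mask_window // 2
    sites = {}
    for r in variants.itertuples(index=False):
        sites.setdefault((r.chrom, r.pos, r.ref, r.alt), []).append(r)
    accepted = []
    for key, rows in sites.items():
        passing = [r for r in rows if r.alt_mq20 >= min_alt_mq20]
        if len(passing) != 1:
            continue
        test = passing[0]
        others = [r for r in rows if r.bulk_id != test.bulk_id]
        if any(r.alt_reads / r.total_reads > tol for r in others):
            continue
        if sum(r.alt_reads for r in others) / (n_bulks - 1) > max_other_mean:
            continue
        accepted.append((key, test.bulk_id))
    # fragment mask: sliding windows per (bulk, chrom)
    final = set()
    for (key, bulk) in accepted:
        chrom, pos = key[0], key[1]
        peers = [k[1] for k, b in accepted if b == bulk and k[0] == chrom]
        L = (chrom_lengths or {}).get(chrom, max(peers) + 1)
        masked = False
        start = 0
        while start < L:
            end = min(start + mask_window, L)
            count = sum(start <= p < end for p in peers)
            if count >= mask_min and start <= pos < end:
                masked = True
            if end >= L:
                break
            start += mask_step
        if not masked:
            final.add((*key, bulk))
    return final


def brute_bin_counts(bins: pd.DataFrame, snps: pd.DataFrame) -> list[int]:
    out = []
    for b in bins.itertuples(index=False):
        n = 0
        for s in snps.itertuples(index=False):
            if s.chrom == b.chrom and b.start <= s.pos < b.end:
                n += 1
        out.append(n)
    return out


def brute_kmer(snps: pd.DataFrame, seqs: dict[str, str],
               offsets: tuple[int, ...]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in snps.itertuples(index=False):
        seq = seqs[s.chrom]
        idx = [s.pos + o for o in offsets]
        if idx[0] < 0 or idx[-1] >= len(seq):
            continue
        kmer = "".join(seq[i] for i in idx)
        if "N" in kmer:
            continue
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def brute_cpg_islands(seq: str, window=100, min_len=200, gc_min=0.5,
                      oe_min=0.6) -> list[tuple[int, int]]:
    """Enumerate every window, mark passing bases, report components >= min_len."""
    L = len(seq)
    covered = [False] * L
    for start in range(0, L - window + 1):
        w = seq[start:start + window]
        n_c, n_g = w.count("C"), w.count("G")
        n_cpg = sum(1 for i in range(window - 1) if w[i:i + 2] == "CG")
        gc_ok = (n_c + n_g) / window >= gc_min
        oe = (n_cpg * window / (n_c * n_g)) if n_c * n_g else 0.0
        if gc_ok and oe >= oe_min:
            for i in range(start, start + window):
                covered[i] = True
    spans = []
    i = 0
    while i < L:
        if covered[i]:
            j = i
            while j < L and covered[j]:
                j += 1
            if j - i >= min_len:
                spans.append((i, j))
            i = j
        else:
            i += 1
    return spans


def brute_merge(intervals: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    """Transitive merge by repeated pairwise passes."""
    items = sorted(intervals)
    changed = True
    while changed:
        changed = False
        out = []
        for s, e in items:
            if out and s - out[-1][1] <= gap:
                out[-1] = (out[-1][0], max(out[-1][1], e))
                changed = True
            else:
                out.append((s, e))
        items = out
    return items


def brute_signal(pos: int, tracks: list[pd.DataFrame], flank: int = 10):
    """(value, source) by scanning the 2*flank+1 window base by base."""
    at = []
    for t in tracks:
        for r in t.itertuples(index=False):
            if r.start <= pos < r.end:
                at.append(r.value)
    if at:
        return max(at), "at_site"
    near = []
    for p in range(pos - flank, pos + flank + 1):
        for t in tracks:
            for r in t.itertuples(index=False):
                if r.start <= p < r.end:
                    near.append(r.value)
    if near:
        return max(near), "flank10"
    return None, "missing"
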
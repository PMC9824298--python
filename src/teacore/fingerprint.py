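"""Probability of identity and minimal discriminating fingerprint panels.

PI is the probability that two random unrelated individuals share a
genotype at a locus under HWE:

    PI = 2 (sum_i p_i^2)^2 - sum_i p_i^4

For a biallelic locus PI is minimised at p = 0.5 (PI = 0.375), so even
the best SNP needs several loci; panels combine multiplicatively under
the independence assumption (unlinked loci), and a k-SNP panel can in
principle separate 2^k allelic states (3^k full genotype states).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .diversity import LocusDiversity
from .genotypes import MISSING, AlleleFreqs, GenotypeMatrix, allele_frequencies


def locus_pi(p: float | np.ndarray) -> float | np.ndarray:
    """Single-locus probability of identity from the allele_a frequency."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    a2 = p**2 + q**2
    a4 = p**4 + q**4
    out = 2.0 * a2**2 - a4
    return float(out) if out.ndim == 0 else out


def combined_pi(pis: Iterable[float]) -> float:
    """Multi-locus PI: the product over independent loci (empty -> 1)."""
    out = 1.0
    for x in pis:
        if not (0.0 < x <= 1.0):
            raise ValueError(f"per-locus PI must be in (0, 1], got {x}")
        out *= x
    return out


def theoretical_capacity(k: int, genotype_states: bool = False) -> int:
    """Number of distinguishable profiles for a k-SNP panel.

    The conventional dimorphic-allele figure is 2^k; with all three
    genotype states counted it is 3^k.
    """
    if k < 0:
        raise ValueError("panel size must be >= 0")
    return (3 if genotype_states else 2) ** k


@dataclass
class PanelSelection:
    """An ordered marker subset with its discrimination bookkeeping."""

    locus_ids: list[str]
    cumulative_pi: list[float]
    distinguishes_all: bool
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)


def _pair_distinction(g: GenotypeMatrix) -> tuple[list[tuple[int, int]], list[int]]:
    """For each locus, a bitmask over sample pairs it distinguishes.

    A locus distinguishes a pair only when both calls are present and
    differ; missing data never counts as distinguishing.
    """
    pairs = list(combinations(range(g.n_samples), 2))
    masks = []
    for j in range(g.n_loci):
        col = g.codes[:, j]
        m = 0
        for b, (s, t) in enumerate(pairs):
            if col[s] != MISSING and col[t] != MISSING and col[s] != col[t]:
                m |= 1 << b
        masks.append(m)
    return pairs, masks


def select_min_panel(
    g: GenotypeMatrix,
    stats: Sequence[LocusDiversity] | None = None,
    strategy: str = "greedy",
    max_loci: int | None = None,
) -> PanelSelection:
    """Choose a marker subset whose joint genotypes separate all samples.

    greedy: rank loci ascending by PI (ties: larger Ho, then locus id)
    and add until every sample pair differs at >= 1 panel locus or loci
    are exhausted.  exhaustive: smallest-cardinality distinguishing
    subset by breadth-first search over subset sizes (<= 20 loci only);
    among equal-size subsets the lowest combined PI wins, ties broken by
    locus-id order.

    Samples with identical full profiles are reported via
    ``duplicate_pairs`` (with ``distinguishes_all`` False), never raised.
    """
    if g.n_samples < 2:
        raise ValueError("panel selection needs >= 2 samples")
    if strategy not in ("greedy", "exhaustive"):
        raise ValueError("strategy must be 'greedy' or 'exhaustive'")
    freqs = allele_frequencies(g)
    pi_by_locus = {lid: float(locus_pi(p)) for lid, p in zip(freqs.locus_ids, freqs.p)}
    if stats is not None:
        ho_by_locus = {s.locus_id: s.ho for s in stats}
    else:
        typed = g.codes != MISSING
        het = g.codes == 1
        ho = het.sum(axis=0) / np.maximum(typed.sum(axis=0), 1)
        ho_by_locus = dict(zip(g.locus_ids, ho.astype(float)))

    pairs, masks = _pair_distinction(g)
    mask_by_locus = dict(zip(g.locus_ids, masks))
    full_mask = (1 << len(pairs)) - 1
    all_union = 0
    for m in masks:
        all_union |= m
    limit = g.n_loci if max_loci is None else min(max_loci, g.n_loci)

    if strategy == "greedy":
        order = sorted(
            g.locus_ids, key=lambda lid: (pi_by_locus[lid], -ho_by_locus[lid], lid)
        )
        chosen: list[str] = []
        covered = 0
        for lid in order:
            if covered == all_union or len(chosen) >= limit:
                break
            chosen.append(lid)
            covered |= mask_by_locus[lid]
    else:
        if g.n_loci > 20:
            raise ValueError("exhaustive search permitted only for <= 20 loci")
        chosen = None
        ids = sorted(g.locus_ids)
        for size in range(1, limit + 1):
            best = None
            for subset in combinations(ids, size):
                u = 0
                for lid in subset:
                    u |= mask_by_locus[lid]
                if u == all_union:
                    key = combined_pi(pi_by_locus[lid] for lid in subset)
                    if best is None or key < best[0]:
                        best = (key, list(subset))
            if best is not None:
                chosen = best[1]
                break
        if chosen is None:
            chosen = ids[:limit]
        # order the chosen subset by the greedy ranking for reporting
        chosen = sorted(
            chosen, key=lambda lid: (pi_by_locus[lid], -ho_by_locus[lid], lid)
        )
        covered = 0
        for lid in chosen:
            covered |= mask_by_locus[lid]

    cum, acc = [], 1.0
    for lid in chosen:
        acc *= pi_by_locus[lid]
        cum.append(acc)
    unresolved = full_mask & ~covered
    duplicate_pairs = [
        (g.samples[pairs[b][0]], g.samples[pairs[b][1]])
        for b in range(len(pairs))
        if unresolved >> b & 1
    ]
    return PanelSelection(
        locus_ids=list(chosen),
        cumulative_pi=cum,
        distinguishes_all=not duplicate_pairs,
        duplicate_pairs=duplicate_pairs,
    )
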
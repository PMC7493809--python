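"""Post-scoring analyses: enrichment curves, overlap, entropy, mechanisms.

Gold-standard *enrichment* at rank k is the precision among the top k ranked
genes divided by the gold-standard's baseline fraction among all ranked
(i.e. mutated) genes; a random ordering has expected enrichment 1 at every
rank. The *normalized Shannon entropy* of a gene's interaction-site mutation
distribution separates hotspot-like genes (entropy near 0, mutations at one
site) from genes whose interfaces are perturbed broadly (entropy near 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import entropy as shannon_entropy
from scipy.stats import rankdata

from .engine import MutationRecord
from .exceptions import InputError
from .tracks import FunctionalTrack

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentCurve:
    """Per-rank gold-standard enrichment for a gene ranking."""

    genes: List[str]
    is_gold: np.ndarray
    enrichment: np.ndarray
    baseline: float

    def at(self, rank: int) -> float:
        """Enrichment among the top ``rank`` genes (1-based)."""
        if not 1 <= rank <= len(self.genes):
            raise InputError(f"rank {rank} outside [1, {len(self.genes)}]")
        return float(self.enrichment[rank - 1])

    def auc(self, top_n: Optional[int] = None) -> float:
        """Trapezoid area under the enrichment curve over the top ranks."""
        top_n = top_n or len(self.genes)
        top_n = min(top_n, len(self.genes))
        ranks = np.arange(1, top_n + 1, dtype=float)
        return float(np.trapezoid(self.enrichment[:top_n], ranks))

    def decimated(self, step: int = 10) -> pd.DataFrame:
        """Every ``step``-th rank (the per-cancer evaluation convention)."""
        idx = np.arange(step - 1, len(self.genes), step)
        return pd.DataFrame(
            {"rank": idx + 1, "enrichment": self.enrichment[idx]}
        )


def enrichment_curve(
    ranking: Sequence[str],
    gold: Set[str],
) -> EnrichmentCurve:
    """Gold-standard enrichment at every rank of a strict gene ordering.

    Gold-standard genes absent from ``ranking`` (unmutated in the cohort)
    are excluded from both the numerator and the baseline.
    """
    genes = list(ranking)
    if len(set(genes)) != len(genes):
        raise InputError("ranking contains duplicate genes")
    if not genes:
        raise InputError("empty ranking")
    is_gold = np.array([g in gold for g in genes], dtype=bool)
    n_gold = int(is_gold.sum())
    baseline = n_gold / len(genes)
    if n_gold == 0:
        logger.warning("no gold-standard genes in the ranking; curve is all zero")
        return EnrichmentCurve(
            genes=genes, is_gold=is_gold,
            enrichment=np.zeros(len(genes)), baseline=0.0,
        )
    ranks = np.arange(1, len(genes) + 1, dtype=float)
    precision = np.cumsum(is_gold) / ranks
    return EnrichmentCurve(
        genes=genes, is_gold=is_gold,
        enrichment=precision / baseline, baseline=baseline,
    )


def jaccard_overlap(top_a: Set[str], top_b: Set[str]) -> float:
    """Jaccard index |A n B| / |A u B| of two top-gene sets."""
    if not top_a and not top_b:
        raise InputError("both gene sets are empty")
    return len(top_a & top_b) / len(top_a | top_b)


def auroc(scores: Sequence[Optional[float]], labels: Sequence[bool]) -> float:
    """Ranking AUROC via the Mann-Whitney statistic (ties averaged).

    ``None``/NaN scores rank below every finite score (unscored genes sit at
    the bottom of the ranking).
    """
    y = np.asarray(labels, dtype=bool)
    s = np.array(
        [(-math.inf if v is None or (isinstance(v, float) and math.isnan(v)) else v)
         for v in scores],
        dtype=float,
    )
    if y.all() or not y.any():
        raise InputError("need both positive and negative labels")
    r = rankdata(s)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = r[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class EntropyResult:
    """Normalized Shannon entropy of mutations over interaction sites."""

    gene: str
    n_sites: int
    n_mutations: int
    site_counts: Dict[int, int]
    entropy: float


def interaction_entropy(
    tracks: Sequence[FunctionalTrack],
    mutations: Sequence[MutationRecord],
    gene: str = "",
) -> EntropyResult:
    """Entropy of the mutation distribution across a gene's interaction sites.

    Sites are the union of positions with nonzero weight over the gene's
    interaction tracks; K = number of such sites normalizes the entropy into
    [0, 1] (0 = all mutations at one site, 1 = uniform over all K sites).
    The normalized value is independent of the logarithm base.
    """
    inter = [t for t in tracks if t.group == "interaction"]
    if not inter:
        raise InputError("no interaction tracks for entropy")
    sites = np.unique(np.concatenate([t.positive_positions for t in inter]))
    if sites.size == 0:
        raise InputError("no positively weighted interaction sites")
    site_set = set(sites.tolist())
    counts: Dict[int, int] = {}
    for m in mutations:
        if m.mutation_class != "missense":
            continue
        p = m.protein_position
        if p in site_set:
            counts[p] = counts.get(p, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise InputError("no missense mutations on interaction sites")
    k = int(sites.size)
    if k == 1:
        h = 0.0
    else:
        p_vec = np.array(list(counts.values()), dtype=float) / total
        h = float(shannon_entropy(p_vec) / math.log(k))
    return EntropyResult(
        gene=gene, n_sites=k, n_mutations=total, site_counts=counts,
        entropy=min(max(h, 0.0), 1.0),
    )


def mechanism_report(
    results,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-gene table of perturbed track groups/ligands.

    Display rules: interaction tracks with Z >= threshold are always listed;
    a domain track is listed only when no interaction track of the same
    domain family reaches the threshold; the conservation track is listed
    only when every other subgene track is below the threshold. Genes where
    nothing reaches the threshold get an empty mechanism row.
    """
    rows = []
    for gene in sorted(results.gene_results):
        gr = results.gene_results[gene]
        bd = [b for b in gr.breakdown if b.group != "natural_variation"]
        inter_hits = [
            b for b in bd if b.group == "interaction"
            and b.zscore is not None and b.zscore >= threshold
        ]
        hit_families = {b.family_id for b in inter_hits if b.family_id}
        domain_hits = [
            b for b in bd if b.group == "domain"
            and b.zscore is not None and b.zscore >= threshold
            and b.family_id not in hit_families
        ]
        mechanisms = [
            f"interaction:{b.ligand or '.'}:{b.track_id}" for b in inter_hits
        ] + [f"domain:{b.track_id}" for b in domain_hits]
        if not mechanisms:
            cons_hits = [
                b for b in bd if b.group == "conservation"
                and b.zscore is not None and b.zscore >= threshold
            ]
            others_below = all(
                b.zscore is None or b.zscore < threshold
                for b in bd if b.group != "conservation"
            )
            if cons_hits and others_below:
                mechanisms = [f"conservation:{b.track_id}" for b in cons_hits]
        rows.append(
            {
                "gene": gene,
                "combined_z": gr.combined_z,
                "mechanisms": ";".join(mechanisms),
                "n_mechanisms": len(mechanisms),
            }
        )
    return pd.DataFrame(rows)
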
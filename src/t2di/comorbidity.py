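"""Comorbidity layer: RR-filtered disease gene sets and symptom similarity.

Relative-risk values are epidemiological input metadata, not estimated
here: diseases pass the comorbidity filter when RR >= 1.5 with the lower
99% confidence bound strictly above 1.0.  Signature genes are then tested
for over-representation in each comorbid disease's gene set (one-sided
Fisher), and disease-disease symptom similarity is the cosine of TF-IDF
weighted symptom-term vectors.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .gwas import fisher_enrichment

logger = logging.getLogger(__name__)

DEFAULT_RR_MIN = 1.5
DEFAULT_CI_LOW_MIN = 1.0


@dataclass(frozen=True)
class ComorbidDisease:
    """A disease with its gene set and relative risk vs the index disease."""

    name: str
    genes: frozenset[str] | set[str]
    rr: float
    rr_ci_low: float

    def __post_init__(self):
        if self.rr <= 0:
            raise ValidationError(f"{self.name}: relative risk must be > 0")


def filter_comorbid(
    diseases: list[ComorbidDisease],
    rr_min: float = DEFAULT_RR_MIN,
    ci_low_min: float = DEFAULT_CI_LOW_MIN,
) -> list[ComorbidDisease]:
    """Keep diseases with rr >= rr_min AND rr_ci_low > ci_low_min (as printed)."""
    return [d for d in diseases if d.rr >= rr_min and d.rr_ci_low > ci_low_min]


def comorbid_gene_enrichment(
    signatures: set[str], disease: ComorbidDisease, universe: set[str]
) -> tuple[int, float, float]:
    """Overlap, odds ratio and one-sided Fisher p of signatures in a disease set.

    The 2x2 table is taken over ``universe``; signature and disease genes
    must both lie inside it.
    """
    if not universe:
        raise ValidationError("universe must be nonempty")
    sig = set(signatures) & universe
    dis = set(disease.genes) & universe
    if sig != set(signatures) or dis != set(disease.genes):
        logger.info(
            "%s: %d signature / %d disease gene(s) outside universe ignored",
            disease.name, len(set(signatures) - sig), len(set(disease.genes) - dis),
        )
    a = len(sig & dis)
    b = len(sig - dis)
    c = len(dis - sig)
    d = len(universe) - a - b - c
    odds, p = fisher_enrichment(a, b, c, d)
    return a, odds, p


def tfidf_similarity(corpus: dict[str, Counter]) -> pd.DataFrame:
    """Pairwise cosine similarity of TF-IDF weighted symptom-term vectors.

    w(t, d) = tf(t, d) * ln(N / n_t) with N diseases and n_t the number of
    diseases containing term t; a term present in every disease gets zero
    weight.  A disease whose whole vector vanishes has similarity 0 to
    everything (flagged in the log), including itself.
    """
    if len(corpus) < 2:
        raise ValidationError("need >= 2 diseases")
    diseases = sorted(corpus)
    for d in diseases:
        if not corpus[d]:
            raise ValidationError(f"disease {d!r} has no terms")
    n = len(diseases)
    terms = sorted({t for d in diseases for t in corpus[d]})
    doc_freq = Counter(t for d in diseases for t in set(corpus[d]))
    idf = {t: math.log(n / doc_freq[t]) for t in terms}
    matrix = np.zeros((n, len(terms)))
    for i, d in enumerate(diseases):
        for j, t in enumerate(terms):
            matrix[i, j] = corpus[d].get(t, 0) * idf[t]
    norms = np.linalg.norm(matrix, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning(
            "disease(s) with all-zero TF-IDF vector: %s; similarity set to 0",
            [diseases[i] for i in np.nonzero(zero)[0]],
        )
    safe = np.where(zero, 1.0, norms)
    sim = (matrix / safe[:, None]) @ (matrix / safe[:, None]).T
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.fill_diagonal(sim, np.where(zero, 0.0, 1.0))
    sim = np.clip(sim, 0.0, 1.0)
    return pd.DataFrame(sim, index=diseases, columns=diseases)


def parse_rr_description(desc: str) -> tuple[float, float]:
    """Parse ``RR=x;CI_LOW=y`` metadata from a GMT description field."""
    fields = dict(part.split("=", 1) for part in desc.split(";") if "=" in part)
    try:
        return float(fields["RR"]), float(fields["CI_LOW"])
    except KeyError as exc:
        raise ValidationError(f"GMT description lacks RR metadata: {desc!r}") from exc
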
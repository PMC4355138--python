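"""Candidate-gene prioritization evaluation with ROC/AUC.

For each disease with a phenotype profile, every gene in the evaluated
corpus is scored by simGIC against the disease's closed profile.  A
(disease, gene) pair is labelled positive when a curated association
asserts it; all other pairs are negatives (no negative sampling).  Pairs
are pooled across diseases into one labelled score list and summarized
with a single ROC curve — the micro-averaged analogue of plotting one
curve per evaluation set — plus a per-disease rank table.

Tied scores are handled as one threshold group (a diagonal ROC segment),
which makes the trapezoidal AUC equal to the tie-corrected Mann–Whitney
U statistic divided by n_pos * n_neg.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .corpus import Corpus, ICTable
from .errors import CorpusFormatError, EvaluationError
from .similarity import QueryProfile, SearchIndex

logger = logging.getLogger(__name__)


@dataclass
class AssociationSet:
    """Curated disease -> entity links used as ROC ground truth."""

    pairs: frozenset  # of (disease_id, entity_id)
    source_label: str = ""
    n_excluded: int = 0

    @property
    def diseases(self) -> frozenset:
        return frozenset(d for d, _ in self.pairs)

    def positives_for(self, disease_id: str) -> frozenset:
        return frozenset(e for d, e in self.pairs if d == disease_id)


def load_associations(
    path,
    corpus: Corpus,
    disease_corpus: Optional[Corpus] = None,
    source_label: str = "",
) -> AssociationSet:
    """Load an association TSV (columns disease_id, entity_id, optional
    ortholog_of) and restrict it to corpus members.

    ``corpus`` is checked for the entity side; the disease side is checked
    against ``disease_corpus`` when given, else against ``corpus`` too.
    Unmatched pairs are excluded with a logged count; zero usable pairs is
    an error.
    """
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise CorpusFormatError(f"association file {path!r} is empty") from exc
    for col in ("disease_id", "entity_id"):
        if col not in frame.columns:
            raise CorpusFormatError(f"association file {path!r} lacks column {col!r}")

    disease_side = disease_corpus if disease_corpus is not None else corpus
    kept: set = set()
    n_excluded = 0
    for disease_id, entity_id in frame[["disease_id", "entity_id"]].itertuples(
        index=False, name=None
    ):
        if disease_id in disease_side and entity_id in corpus:
            kept.add((disease_id, entity_id))
        else:
            n_excluded += 1
    if n_excluded:
        logger.warning(
            "excluded %d association pair(s) not present in the corpus", n_excluded
        )
    if not kept:
        raise CorpusFormatError(
            f"association file {path!r} shares no usable pairs with the corpus"
        )
    return AssociationSet(
        pairs=frozenset(kept),
        source_label=source_label or str(path),
        n_excluded=n_excluded,
    )


def rank_based_labels(
    associations: AssociationSet,
    disease_profiles: Corpus,
    gene_corpus: Corpus,
    ic: ICTable,
) -> list:
    """Score all (disease, gene) pairs and label them against the curated
    associations.

    For each disease with a phenotype profile, every gene in
    ``gene_corpus`` is scored by simGIC against the disease's closed
    profile; the pair is positive iff asserted in ``associations``.  All
    pairs are pooled into one ``[(score, is_positive), ...]`` list.
    Diseases without a profile are skipped with a warning.
    """
    index = SearchIndex(gene_corpus, ic)
    labelled: list = []
    for disease_id in sorted(associations.diseases):
        profile = disease_profiles.profiles.get(disease_id)
        if profile is None:
            logger.warning("disease %s has no phenotype profile; skipped", disease_id)
            continue
        positives = associations.positives_for(disease_id)
        query = QueryProfile(
            raw_terms=tuple(sorted(profile.annotated_terms)),
            effective_terms=profile.annotated_terms,
            closed_terms=profile.closed_terms,
        )
        result = index.search(query)
        for entity_id, _etype, _species, score in result.entries:
            labelled.append((score, entity_id in positives))
    return labelled


def per_disease_ranks(
    associations: AssociationSet,
    disease_profiles: Corpus,
    gene_corpus: Corpus,
    ic: ICTable,
) -> pd.DataFrame:
    """Rank of each true gene within its disease's ranking (1 = best;
    ties share the mean of their rank range), with a per-disease median.

    Columns: disease_id, entity_id, rank, n_candidates, median_rank.
    """
    index = SearchIndex(gene_corpus, ic)
    rows = []
    for disease_id in sorted(associations.diseases):
        profile = disease_profiles.profiles.get(disease_id)
        if profile is None:
            continue
        query = QueryProfile(
            raw_terms=tuple(sorted(profile.annotated_terms)),
            effective_terms=profile.annotated_terms,
            closed_terms=profile.closed_terms,
        )
        result = index.search(query)
        scores = np.array(result.scores())
        # mean rank over each tie group, 1-based from the top score
        ranks = rankdata(-scores, method="average")
        id_to_rank = dict(zip(result.entity_ids(), ranks))
        positive_ranks = [
            id_to_rank[g] for g in sorted(associations.positives_for(disease_id))
            if g in id_to_rank
        ]
        median = float(np.median(positive_ranks)) if positive_ranks else float("nan")
        for gene, rank in zip(
            sorted(g for g in associations.positives_for(disease_id) if g in id_to_rank),
            positive_ranks,
        ):
            rows.append(
                {
                    "disease_id": disease_id,
                    "entity_id": gene,
                    "rank": float(rank),
                    "n_candidates": len(result),
                    "median_rank": median,
                }
            )
    return pd.DataFrame(rows, columns=["disease_id", "entity_id", "rank", "n_candidates", "median_rank"])


@dataclass
class RocCurve:
    """ROC points (FPR, TPR ascending from (0,0) to (1,1)) and trapezoidal
    AUC."""

    points: list  # of (fpr, tpr)
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["fpr", "tpr"])


def roc(labelled: Sequence[tuple]) -> RocCurve:
    """Build the ROC curve of a pooled ``(score, is_positive)`` list.

    Threshold sweep over distinct scores descending; tied scores form one
    group.  AUC by the trapezoidal rule, which under tie grouping equals
    the tie-corrected Mann–Whitney statistic U / (n_pos * n_neg).
    Requires at least one positive and one negative label.
    """
    if not labelled:
        raise EvaluationError("empty labelled score list")
    scores = np.asarray([s for s, _ in labelled], dtype=float)
    labels = np.asarray([bool(l) for _, l in labelled], dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError(
            f"need both classes to draw a ROC curve (got {n_pos} positives, {n_neg} negatives)"
        )
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return RocCurve(points=points, auc=auc)


def write_roc(curve: RocCurve, points_path, summary_path) -> None:
    """Write the points TSV (fpr, tpr) and a summary line ``AUC<TAB>value``."""
    curve.to_frame().to_csv(points_path, sep="\t", index=False, float_format="%.6f")
    with open(summary_path, "w") as handle:
        handle.write(f"AUC\t{curve.auc:.6f}\n")
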
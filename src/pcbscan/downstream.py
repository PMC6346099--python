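"""Stratified orchestration and downstream interpretation stages.

Runs the interaction scans over a grid of congeners x cell types within
population strata (all / by sex / by sex and future case status), compares
exposure levels between sexes, intersects hit lists with externally supplied
known-gene sets, performs hypergeometric over-representation analysis,
builds a differential-expression signature, and correlates batch-corrected
expression of hits with time to diagnosis in future cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import lmm
from .design import confounder_matrix, pcb_column, transform_exposure
from .lmm import bh_fdr
from .scan import ScanSpec, _align, interaction_scan, scan
from .simulate import CELL_TYPES, CONGENERS, PCB_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_MIN_STRATUM_N = 30


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset
    source: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# stratified scan counts


def stratified_scan_counts(
    expression: pd.DataFrame,
    cohort: pd.DataFrame,
    congeners=CONGENERS,
    cell_types=CELL_TYPES,
    spec: ScanSpec | None = None,
    by_case_status: bool = True,
    min_n: int = DEFAULT_MIN_STRATUM_N,
) -> pd.DataFrame:
    """Significant-transcript counts per (sex, cell type, congener) cell.

    For every sex stratum and grid cell, the interaction scan is run
    separately in controls and future cases; the table reports both counts
    and the overlap of the two significant sets.  With ``cell_types=None``
    exposure-only scans are run instead (single-count table).  Strata below
    ``min_n`` subjects yield NA counts with a logged reason.
    """
    spec = spec or ScanSpec()
    rows = []
    for sex in ("F", "M"):
        sex_cohort = cohort[cohort["sex"] == sex]
        for cell in cell_types if cell_types is not None else (None,):
            for congener in congeners:
                row = {
                    "population": "Females" if sex == "F" else "Males",
                    "cell_type": cell if cell else "",
                    "pcb": congener,
                }
                if by_case_status:
                    sets = {}
                    for label, is_case in (("controls", False), ("future_cases", True)):
                        sub = sex_cohort[sex_cohort["future_case"] == is_case]
                        sets[label] = _significant_set(
                            expression, sub, congener, cell, spec, min_n,
                            stratum=f"sex={sex},case={is_case}",
                        )
                    row["controls"] = _count(sets["controls"])
                    row["overlap"] = (
                        len(sets["controls"] & sets["future_cases"])
                        if sets["controls"] is not None
                        and sets["future_cases"] is not None
                        else np.nan
                    )
                    row["future_cases"] = _count(sets["future_cases"])
                else:
                    hits = _significant_set(
                        expression, sex_cohort, congener, cell, spec, min_n,
                        stratum=f"sex={sex}",
                    )
                    row["n_significant"] = _count(hits)
                rows.append(row)
    return pd.DataFrame(rows)


def _count(s):
    return len(s) if s is not None else np.nan


def _significant_set(expression, sub, congener, cell, spec, min_n, stratum):
    if len(sub) < min_n:
        logger.warning("stratum %s below minimum size (%d < %d); marked NA",
                       stratum, len(sub), min_n)
        return None
    sub = sub.reset_index(drop=True)
    try:
        if cell is None:
            res = scan(expression, sub, pcb_column(congener), spec, stratum)
        else:
            res = interaction_scan(expression, sub, congener, cell, spec, stratum)
    except ValueError as exc:
        logger.warning("scan failed in stratum %s: %s", stratum, exc)
        return None
    return res.significant


# ---------------------------------------------------------------------------
# exposure comparison between sexes


def exposure_sex_ttest(
    cohort: pd.DataFrame,
    transform: str = "log+zscore",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sample t-test of each congener's level between females and males.

    Applied on the same exposure transform the scans use (the z-score step
    is affine and leaves t unchanged; the log matters).  Welch by default.
    """
    present = set(cohort["sex"])
    if not {"F", "M"} <= present:
        raise ValueError(f"both sexes required; found {sorted(present)}")
    rows = []
    for congener, col in zip(CONGENERS, PCB_COLUMNS):
        x = transform_exposure(cohort[col], transform)
        t, p = stats.ttest_ind(
            x[(cohort["sex"] == "F").to_numpy()],
            x[(cohort["sex"] == "M").to_numpy()],
            equal_var=equal_var,
        )
        rows.append({"pcb": congener, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows).set_index("pcb")


# ---------------------------------------------------------------------------
# gene-list comparison and over-representation


def gene_list_overlap(hits: GeneSet, known: GeneSet):
    """Overlap of a hit list with an externally curated gene list.

    Returns (n_overlap, fraction_of_hits, novel GeneSet-or-None); ``novel``
    is None when every hit is already known.
    """
    inter = hits.genes & known.genes
    novel_genes = hits.genes - known.genes
    novel = (
        GeneSet(name=f"{hits.name}_novel", genes=frozenset(novel_genes),
                source=hits.source)
        if novel_genes
        else None
    )
    return len(inter), len(inter) / len(hits.genes), novel


def ora_hypergeometric(
    hits: GeneSet, pathways, background: GeneSet
) -> pd.DataFrame:
    """Hypergeometric over-representation of a hit list in each pathway.

    p is the upper-tail probability of drawing at least the observed overlap
    when |hits| genes are sampled from the background without replacement;
    q is BH across the supplied pathway collection.  Pathways are clipped to
    the background universe first.
    """
    if isinstance(pathways, GeneSet):
        pathways = [pathways]
    if not hits.genes <= background.genes:
        raise ValueError("hits must be a subset of the background universe")
    n_bg = len(background.genes)
    n_hits = len(hits.genes)
    rows = []
    for pw in pathways:
        members = pw.genes & background.genes
        if not members:
            raise ValueError(f"pathway {pw.name!r} has no genes in the background")
        overlap = len(hits.genes & members)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(members), n_hits))
        rows.append(
            {"pathway": pw.name, "pathway_size": len(members),
             "overlap": overlap, "p": min(p, 1.0)}
        )
    table = pd.DataFrame(rows).set_index("pathway")
    table["q"], _ = bh_fdr(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# differential-expression signature


def diff_expr_signature(
    expression: pd.DataFrame,
    group_labels,
    fc_cut: float = 1.5,
    q_cut: float = 0.05,
    tail_frac: float = 0.05,
):
    """Welch-t differential expression plus a top/bottom fold-change signature.

    ``expression`` is genes x subjects on the log2 scale; ``group_labels``
    is a boolean-like vector (True = case group).  A gene is significant
    when |fold change| >= fc_cut and BH q <= q_cut; the signature keeps the
    significant genes inside the top and bottom ``tail_frac`` of log2 fold
    change.  Returns (per-gene table, up GeneSet or None, down GeneSet or
    None).
    """
    labels = np.asarray(group_labels, dtype=bool)
    if labels.shape[0] != expression.shape[1]:
        raise ValueError("group_labels length must match number of subjects")
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if min(n0, n1) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if not 0 < tail_frac <= 0.5:
        raise ValueError("tail_frac must be in (0, 0.5]")
    X = expression.to_numpy(float)
    a, b = X[:, labels], X[:, ~labels]
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    q, _ = bh_fdr(p)
    significant = (np.abs(log2fc) >= np.log2(fc_cut)) & (q <= q_cut)
    table = pd.DataFrame(
        {"log2_fc": log2fc, "fold_change": 2.0**log2fc, "t": t, "p": p, "q": q,
         "significant": significant},
        index=expression.index,
    )
    hi = np.quantile(log2fc, 1.0 - tail_frac)
    lo = np.quantile(log2fc, tail_frac)
    up = table.index[significant & (log2fc >= hi)]
    down = table.index[significant & (log2fc <= lo)]
    up_set = GeneSet("signature_up", frozenset(up)) if len(up) else None
    down_set = GeneSet("signature_down", frozenset(down)) if len(down) else None
    return table, up_set, down_set


# ---------------------------------------------------------------------------
# time to diagnosis


def remove_batch_effects(
    expression: pd.DataFrame, cohort: pd.DataFrame, spec: ScanSpec | None = None
) -> pd.DataFrame:
    """Subtract estimated batch random intercepts (BLUPs) from expression.

    Per transcript, the confounder-only LMM is fitted and the empirical-Bayes
    batch prediction u_a = lam * n_a / (1 + lam * n_a) * mean residual of
    batch a is removed.
    """
    spec = spec or ScanSpec()
    conf, _ = confounder_matrix(
        cohort, spec.confounders, spec.include_wbc, spec.drop_granulocytes
    )
    X = np.column_stack([np.ones(len(cohort)), conf.to_numpy(float)])
    Y = _align(expression, cohort).to_numpy(float)
    codes, _ = pd.factorize(cohort[spec.batch])
    res = lmm._profile_ml(Y, X, codes)
    resid = Y - res["beta"] @ X.T
    B = codes.max() + 1
    nj = np.bincount(codes, minlength=B).astype(float)
    batch_mean = np.stack(
        [np.bincount(codes, weights=resid[t], minlength=B) for t in range(Y.shape[0])]
    ) / nj
    shrink = res["lam"][:, None] * nj / (1.0 + res["lam"][:, None] * nj)
    blup = shrink * batch_mean
    corrected = Y - blup[:, codes]
    return pd.DataFrame(corrected, index=expression.index, columns=cohort["subject_id"])


def ttd_correlation(
    expression_hits: pd.DataFrame,
    time_to_diagnosis,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation of (batch-corrected) hit expression with time to diagnosis.

    ``expression_hits`` is genes x future-case subjects.  Genes with constant
    expression (or a constant time vector) return NA with a logged reason.
    """
    ttd = np.asarray(time_to_diagnosis, dtype=float)
    if ttd.shape[0] != expression_hits.shape[1]:
        raise ValueError("time_to_diagnosis length must match subjects")
    if ttd.shape[0] < 3:
        raise ValueError("need at least 3 future cases")
    if np.isnan(ttd).any():
        raise ValueError("time_to_diagnosis contains missing values")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    const_time = np.std(ttd) == 0
    for gene, row in expression_hits.iterrows():
        x = row.to_numpy(float)
        if const_time or np.std(x) == 0:
            logger.warning("constant input for gene %s; correlation set NA", gene)
            rows.append({"gene": gene, "r": np.nan, "p": np.nan})
            continue
        r, p = corr(x, ttd)
        rows.append({"gene": gene, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows).set_index("gene")
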
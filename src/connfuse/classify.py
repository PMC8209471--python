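"""Feature fusion, Fisher-score selection, LOOCV linear SVM, and the
permutation / rank-based statistics around the classifier.

Undirected (PLI) and directed (PDC) connectivity features are fused
into one subjects x features table (190 + 380 = 570 columns for the
20-channel montage).  Features are ranked by the two-class Fisher score
F = (mu1 - mu2)^2 / (s1^2 + s2^2); classification uses a linear SVM
under leave-one-out cross-validation with per-fold standardization.
Three selection strategies are searched: top-N undirected only, top-N
directed only, and a combined top-n + top-m grid.  Classifier
significance uses a permutation scheme that independently shuffles each
feature column; per-feature group differences use the rank-sum test
with Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from ._exceptions import ValidationError
from .mvar import PDC_TAG, PDCMatrix, vectorize_directed
from .pli import PLI_TAG, PLIMatrix, vectorize_upper

#: Cap applied when class variances vanish but class means differ.
_FISHER_CAP = 1e12


@dataclass
class FeatureTable:
    """Subjects x features with invertible descriptors and group labels."""

    values: np.ndarray
    descriptors: list[tuple[str, str, str]]
    labels: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValidationError("values must be subjects x features")
        if self.values.shape[1] != len(self.descriptors):
            raise ValidationError("descriptor count must match feature columns")
        if self.values.shape[0] != self.labels.size:
            raise ValidationError("label count must match subject rows")
        if not np.isfinite(self.values).all():
            raise ValidationError("feature table contains non-finite values")

    def columns_of(self, estimator: str) -> np.ndarray:
        """Column indices whose descriptor tag equals ``estimator``."""
        idx = np.array([i for i, d in enumerate(self.descriptors)
                        if d[0] == estimator], dtype=int)
        if idx.size == 0:
            raise ValidationError(f"no features of estimator {estimator!r}")
        return idx


def build_feature_table(
    pli_list: list[PLIMatrix],
    pdc_list: list[PDCMatrix],
    labels: list[str] | np.ndarray,
    subject_ids: list[str] | None = None,
) -> FeatureTable:
    """Fuse per-subject PLI and PDC matrices into one feature table.

    Column order is fixed: all upper-triangle PLI features first, then
    all ordered-pair PDC features.
    """
    if len(pli_list) != len(pdc_list) or len(pli_list) != len(labels):
        raise ValidationError("pli_list, pdc_list and labels must align")
    montage = pli_list[0].montage
    for m in pli_list + pdc_list:
        if m.montage.labels != montage.labels:
            raise ValidationError("all matrices must share one montage")
    rows, descriptors = [], None
    for pli_m, pdc_m in zip(pli_list, pdc_list):
        feats = vectorize_upper(pli_m) + vectorize_directed(pdc_m)
        if descriptors is None:
            descriptors = [d for d, _ in feats]
        rows.append([v for _, v in feats])
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(len(rows))]
    return FeatureTable(
        values=np.asarray(rows), descriptors=descriptors,
        labels=np.asarray(labels), subject_ids=list(subject_ids),
    )


def format_descriptor(d: tuple[str, str, str]) -> str:
    """Human-readable feature name: ``A->B`` (directed) or ``A-B``."""
    tag, a, b = d
    return f"{a}->{b}" if tag == PDC_TAG else f"{a}-{b}"


def parse_descriptor(name: str) -> tuple[str, str, str]:
    if "->" in name:
        a, b = name.split("->", 1)
        return (PDC_TAG, a, b)
    a, b = name.split("-", 1)
    return (PLI_TAG, a, b)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write the table as TSV: subject_id, group, then one feature column."""
    import pandas as pd

    df = pd.DataFrame(table.values,
                      columns=[format_descriptor(d) for d in table.descriptors])
    df.insert(0, "group", table.labels)
    df.insert(0, "subject_id", table.subject_ids)
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> FeatureTable:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValidationError(f"feature table {path} lacks column {col!r}")
    feat_cols = [c for c in df.columns if c not in ("subject_id", "group")]
    return FeatureTable(
        values=df[feat_cols].to_numpy(dtype=float),
        descriptors=[parse_descriptor(c) for c in feat_cols],
        labels=df["group"].to_numpy(),
        subject_ids=df["subject_id"].astype(str).tolist(),
    )


@dataclass
class FisherRanking:
    scores: np.ndarray
    order: np.ndarray  # feature indices by descending score, stable ties


def fisher_score(values: np.ndarray, labels: np.ndarray) -> FisherRanking:
    """Two-class Fisher score per feature.

    F = (mu1 - mu2)^2 / (s1^2 + s2^2) with unbiased class variances.
    Both variances zero: F = 0 if the means agree, else a large cap.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError(f"need exactly two classes, got {classes.size}")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    if len(a) < 1 or len(b) < 1:
        raise ValidationError("both classes must be non-empty")
    num = (a.mean(axis=0) - b.mean(axis=0)) ** 2
    var_a = a.var(axis=0, ddof=1) if len(a) > 1 else np.zeros(values.shape[1])
    var_b = b.var(axis=0, ddof=1) if len(b) > 1 else np.zeros(values.shape[1])
    denom = var_a + var_b
    scores = np.where(
        denom > 0, np.divide(num, denom, out=np.zeros_like(num), where=denom > 0),
        np.where(num > 0, _FISHER_CAP, 0.0),
    )
    order = np.argsort(-scores, kind="stable")
    return FisherRanking(scores=scores, order=order)


@dataclass
class CVResult:
    """Pooled leave-one-out performance of one feature selection."""

    acc: float  # percent
    spe: float  # percent
    sen: float  # percent
    auc: float
    predictions: np.ndarray
    decision_values: np.ndarray
    selected: list  # descriptors (or column indices) used
    strategy: str
    n_features: int
    split: tuple[int, int] | None = None  # (n undirected, m directed)
    positive_class: str = ""


def _fold_metrics(labels: np.ndarray, preds: np.ndarray, decisions: np.ndarray,
                  positive_class: str) -> tuple[float, float, float, float]:
    pos = labels == positive_class
    acc = 100.0 * float(np.mean(preds == labels))
    sen = 100.0 * float(np.mean(preds[pos] == labels[pos]))
    spe = 100.0 * float(np.mean(preds[~pos] == labels[~pos]))
    auc = float(roc_auc_score(pos.astype(int), decisions))
    return acc, spe, sen, auc


def loocv_svm(
    values: np.ndarray,
    labels: np.ndarray,
    positive_class: str,
    C: float = 1.0,
    column_selector=None,
) -> CVResult:
    """Leave-one-out linear SVM with per-fold standardization.

    ``column_selector(train_values, train_labels) -> column indices``
    optionally re-selects features inside each training fold (no
    leakage); when omitted all supplied columns are used.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n = values.shape[0]
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValidationError("need two classes with >= 2 subjects each")
    if positive_class not in classes:
        raise ValidationError(f"positive class {positive_class!r} not in labels")
    preds = np.empty(n, dtype=labels.dtype)
    decisions = np.empty(n)
    import sklearn

    with sklearn.config_context(assume_finite=True):
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            x_tr, y_tr = values[mask], labels[mask]
            if np.unique(y_tr).size < 2:
                raise ValidationError("degenerate training fold (single class)")
            cols = (slice(None) if column_selector is None
                    else np.asarray(column_selector(x_tr, y_tr)))
            # training-fold standardization (zero-variance columns untouched)
            xt = x_tr[:, cols]
            mu = xt.mean(axis=0)
            sd = xt.std(axis=0)
            sd[sd == 0] = 1.0
            clf = SVC(kernel="linear", C=C)
            clf.fit((xt - mu) / sd, y_tr)
            x_te = (values[i, cols] - mu) / sd
            d = float(clf.decision_function(x_te[np.newaxis, :])[0])
            preds[i] = clf.classes_[int(d > 0)]
            # orient decision values toward the positive class
            decisions[i] = d if clf.classes_[1] == positive_class else -d
    acc, spe, sen, auc = _fold_metrics(labels, preds, decisions, positive_class)
    return CVResult(
        acc=acc, spe=spe, sen=sen, auc=auc, predictions=preds,
        decision_values=decisions, selected=[], strategy="",
        n_features=values.shape[1], positive_class=positive_class,
    )


def _better(cand: CVResult, best: CVResult | None,
            key=lambda r: (r.n_features,)) -> bool:
    """Max ACC; ties -> smaller size key, then higher AUC."""
    if best is None:
        return True
    if cand.acc != best.acc:
        return cand.acc > best.acc
    if key(cand) != key(best):
        return key(cand) < key(best)
    return cand.auc > best.auc


def select_and_classify_single(
    table: FeatureTable,
    estimator: str,
    n_max: int = 50,
    positive_class: str = "SZ",
    C: float = 1.0,
    rank_on_full_data: bool = False,
) -> CVResult:
    """Best top-N selection (N = 1..n_max) for one estimator's features.

    By default the Fisher ranking is recomputed inside every training
    fold; ``rank_on_full_data=True`` ranks once on all subjects before
    cross-validation, mirroring the common (leakier) published practice.
    """
    if n_max < 1:
        raise ValidationError("n_max must be >= 1")
    cols = table.columns_of(estimator)
    if n_max > cols.size:
        raise ValidationError(
            f"n_max {n_max} exceeds the {cols.size} features of {estimator}"
        )
    sub = table.values[:, cols]
    global_order = fisher_score(sub, table.labels).order if rank_on_full_data else None
    best = None
    for n_feat in range(1, n_max + 1):
        if rank_on_full_data:
            result = loocv_svm(sub[:, global_order[:n_feat]], table.labels,
                               positive_class, C)
            chosen = global_order[:n_feat]
        else:
            selector = (lambda x, y, k=n_feat: fisher_score(x, y).order[:k])
            result = loocv_svm(sub, table.labels, positive_class, C,
                               column_selector=selector)
            # report the full-data ranking as the nominal selection
            chosen = fisher_score(sub, table.labels).order[:n_feat]
        result.strategy = estimator
        result.n_features = n_feat
        result.selected = [table.descriptors[cols[j]] for j in chosen]
        if _better(result, best):
            best = result
    return best


def select_and_classify_combined(
    table: FeatureTable,
    l_max: int = 50,
    positive_class: str = "SZ",
    C: float = 1.0,
    rank_on_full_data: bool = False,
    undirected_tag: str = PLI_TAG,
    directed_tag: str = PDC_TAG,
) -> CVResult:
    """Best combined selection over L = 2..l_max and splits n + m = L.

    For every total L the top-n undirected and top-m directed features
    (n = 1..L-1, m = L-n) are fused and cross-validated; the maximizing
    result records its (n, m) split.  Ties prefer smaller L, then
    smaller n, then higher AUC.
    """
    if l_max < 2:
        raise ValidationError("l_max must be >= 2")
    if l_max > len(table.descriptors):
        raise ValidationError(
            f"l_max {l_max} exceeds the {len(table.descriptors)} features available"
        )
    cols_u = table.columns_of(undirected_tag)
    cols_d = table.columns_of(directed_tag)
    if rank_on_full_data:
        order_u = fisher_score(table.values[:, cols_u], table.labels).order
        order_d = fisher_score(table.values[:, cols_d], table.labels).order
    best = None
    key = lambda r: (r.n_features, r.split[0])
    for L in range(2, l_max + 1):
        for n_u in range(1, L):
            m_d = L - n_u
            if n_u > cols_u.size or m_d > cols_d.size:
                continue
            if rank_on_full_data:
                sel = np.concatenate([cols_u[order_u[:n_u]], cols_d[order_d[:m_d]]])
                result = loocv_svm(table.values[:, sel], table.labels,
                                   positive_class, C)
                chosen = sel
            else:
                def selector(x, y, nu=n_u, md=m_d):
                    ou = fisher_score(x[:, cols_u], y).order[:nu]
                    od = fisher_score(x[:, cols_d], y).order[:md]
                    return np.concatenate([cols_u[ou], cols_d[od]])
                result = loocv_svm(table.values, table.labels, positive_class,
                                   C, column_selector=selector)
                ou = fisher_score(table.values[:, cols_u], table.labels).order[:n_u]
                od = fisher_score(table.values[:, cols_d], table.labels).order[:m_d]
                chosen = np.concatenate([cols_u[ou], cols_d[od]])
            result.strategy = "combined"
            result.n_features = L
            result.split = (n_u, m_d)
            result.selected = [table.descriptors[j] for j in chosen]
            if _better(result, best, key=key):
                best = result
    if best is None:
        raise ValidationError("no feasible (n, m) split under l_max")
    return best


@dataclass
class PermTestResult:
    p_value: float
    null_accs: np.ndarray
    observed_acc: float
    n_perm: int
    smoothed: bool


def modified_permutation_test(
    values: np.ndarray,
    labels: np.ndarray,
    positive_class: str,
    n_perm: int = 10_000,
    seed: int = 0,
    C: float = 1.0,
    smoothed: bool = True,
) -> PermTestResult:
    """Classifier significance by independent per-feature permutation.

    Each permutation shuffles every feature column independently
    (destroying both feature-label and feature-feature alignment), runs
    the full LOOCV and records its accuracy.  The p value is the
    fraction of null accuracies >= the observed one, by default with
    add-one smoothing ((1 + count) / (1 + n_perm)) so p is never zero.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    observed = loocv_svm(values, labels, positive_class, C).acc
    n, f = values.shape
    null = np.empty(n_perm)
    cols = np.arange(f)
    for k in range(n_perm):
        idx = rng.random((n, f)).argsort(axis=0)  # independent column shuffles
        null[k] = loocv_svm(values[idx, cols], labels, positive_class, C).acc
    count = int(np.sum(null >= observed))
    p = (1 + count) / (1 + n_perm) if smoothed else count / n_perm
    return PermTestResult(p_value=p, null_accs=null, observed_acc=observed,
                          n_perm=n_perm, smoothed=smoothed)


@dataclass
class FeatureComparison:
    descriptor: tuple | int
    mean_sem: dict  # group -> (mean, sem)
    direction: str  # "up" if first group's median exceeds the second's
    p_raw: float
    p_fdr: float
    significant: bool


def compare_selected_features(
    values: np.ndarray,
    labels: np.ndarray,
    alpha_fdr: float = 0.05,
    descriptors: list | None = None,
    group_order: tuple[str, str] | None = None,
) -> list[FeatureComparison]:
    """Rank-based two-sample comparison per feature with BH-FDR correction.

    Groups are independent, so the rank-sum (Mann-Whitney) test is used.
    Direction is the sign of the first group's median minus the
    second's ("up" = higher in the first group).  Features whose values
    are all identical get p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if group_order is None:
        group_order = tuple(np.unique(labels))  # type: ignore[assignment]
    g1, g2 = group_order
    a = values[labels == g1]
    b = values[labels == g2]
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    n_feat = values.shape[1]
    p_raw = np.ones(n_feat)
    direction = []
    for j in range(n_feat):
        if np.ptp(values[:, j]) == 0:
            p_raw[j] = 1.0
        else:
            p_raw[j] = stats.mannwhitneyu(a[:, j], b[:, j],
                                          alternative="two-sided").pvalue
        diff = np.median(a[:, j]) - np.median(b[:, j])
        direction.append("up" if diff > 0 else ("down" if diff < 0 else "none"))
    reject, p_fdr, _, _ = multipletests(p_raw, alpha=alpha_fdr, method="fdr_bh")
    sem = lambda x: float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    out = []
    for j in range(n_feat):
        out.append(FeatureComparison(
            descriptor=descriptors[j] if descriptors is not None else j,
            mean_sem={g1: (float(a[:, j].mean()), sem(a[:, j])),
                      g2: (float(b[:, j].mean()), sem(b[:, j]))},
            direction=direction[j],
            p_raw=float(p_raw[j]),
            p_fdr=float(p_fdr[j]),
            significant=bool(reject[j]),
        ))
    return out
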
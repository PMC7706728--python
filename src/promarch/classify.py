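"""Rule-based tissue-specificity classification of sites and genes.

Accessible sites (RPM) and genes (TPM) are classified across five
tissues — germline, neurons, muscle, hypodermis, intestine — from a
replicate-averaged signal matrix plus a table of pairwise differential
statistics (fold change and adjusted P-value, computed upstream by a
count-based differential test). The decision tree:

0. signal below the detection threshold in every tissue -> unclassified;
1. *specific(t)*: t has the maximal signal and is significantly higher
   (FC > 3, padj < 0.01) than each of the four other tissues;
2. *restricted(T)*: the detected tissue set T has 2-4 members, every
   member is significantly higher than every non-member, and no member
   dominates all other members;
3. detected in all five, max/min signal < 3 and no significant pair
   -> ubiquitous-uniform;
4. detected in all five otherwise -> ubiquitous-biased;
5. anything else -> unclassified.

Default thresholds: 8 RPM (sites) / 5 TPM (genes) detection, fold
change 3, adjusted P 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: The five profiled tissues, in canonical order.
TISSUES = ("germline", "neurons", "muscle", "hypodermis", "intestine")


@dataclass(frozen=True)
class SpecificityLabel:
    """A tissue-specificity class.

    ``category`` is one of ``specific``, ``restricted``,
    ``ubiquitous-uniform``, ``ubiquitous-biased``, ``unclassified``;
    ``tissues`` carries the single tissue (specific) or the detected
    subset (restricted).
    """

    category: str
    tissues: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        allowed = {"specific", "restricted", "ubiquitous-uniform",
                   "ubiquitous-biased", "unclassified"}
        if self.category not in allowed:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "specific" and len(self.tissues) != 1:
            raise ValueError("specific label needs exactly one tissue")
        if self.category == "restricted" and not 2 <= len(self.tissues) <= 4:
            raise ValueError("restricted label needs 2-4 tissues")

    def __str__(self) -> str:
        if self.tissues:
            return f"{self.category}:{'+'.join(sorted(self.tissues))}"
        return self.category

    @classmethod
    def parse(cls, text: str) -> "SpecificityLabel":
        if ":" in text:
            cat, tis = text.split(":", 1)
            return cls(cat, frozenset(tis.split("+")))
        return cls(text)


class DiffTable:
    """Pairwise differential statistics, one row per (id, tissue pair).

    ``fold_change`` is the magnitude of the between-tissue ratio
    (>= 1 after symmetrization; the direction of the effect is taken
    from the signal matrix). Pairs are stored unordered.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"id", "tissue_a", "tissue_b", "fold_change", "padj"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"differential table missing columns {sorted(missing)}")
        t = table.copy()
        fc = t["fold_change"].astype(float)
        if (fc <= 0).any():
            raise ValueError("fold changes must be > 0")
        t["fold_change"] = np.maximum(fc, 1.0 / fc)
        key_a = t["tissue_a"].where(t["tissue_a"] < t["tissue_b"], t["tissue_b"])
        key_b = t["tissue_b"].where(t["tissue_a"] < t["tissue_b"], t["tissue_a"])
        self._map: dict[tuple[str, str, str], tuple[float, float]] = {
            (i, a, b): (f, p)
            for i, a, b, f, p in zip(t["id"], key_a, key_b, t["fold_change"], t["padj"])
        }

    def lookup(self, id_: str, tissue_a: str, tissue_b: str) -> tuple[float, float]:
        a, b = sorted((tissue_a, tissue_b))
        try:
            return self._map[(id_, a, b)]
        except KeyError:
            raise KeyError(
                f"no differential statistics for id {id_!r}, pair ({a}, {b})"
            ) from None

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DiffTable":
        return cls(pd.read_csv(path, sep="\t"))


def _classify_one(
    vals: pd.Series,
    sig,  # sig(a, b) -> True if the pair differs significantly
    detect_threshold: float,
    fc_threshold: float,
) -> SpecificityLabel:
    detected = set(vals.index[vals >= detect_threshold])
    if not detected:
        return SpecificityLabel("unclassified")

    # (1) specific: the top tissue beats every other tissue significantly
    top = vals.idxmax()
    if all(sig(top, u) and vals[top] > vals[u] for u in vals.index if u != top):
        return SpecificityLabel("specific", frozenset({top}))

    # (2) restricted: detected subset separated from the rest, internally mixed
    if 2 <= len(detected) <= 4:
        outside = set(vals.index) - detected
        separated = all(
            sig(t, u) and vals[t] > vals[u] for t in detected for u in outside
        )
        no_dominant = all(
            not all(sig(t, u) for u in detected - {t}) for t in detected
        )
        if separated and no_dominant:
            return SpecificityLabel("restricted", frozenset(detected))

    if len(detected) == len(vals):
        any_sig = any(
            sig(a, b) for i, a in enumerate(vals.index) for b in vals.index[i + 1:]
        )
        spread = vals.max() / vals.min() if vals.min() > 0 else np.inf
        # (3) uniform: under threefold spread and no significant pair
        if spread < fc_threshold and not any_sig:
            return SpecificityLabel("ubiquitous-uniform")
        # (4) everywhere-detected but tilted
        return SpecificityLabel("ubiquitous-biased")

    return SpecificityLabel("unclassified")


def classify(
    matrix: pd.DataFrame,
    diffs: DiffTable,
    detect_threshold: float = 8.0,
    fc_threshold: float = 3.0,
    padj_threshold: float = 0.01,
) -> pd.Series:
    """Classify every row of a signal matrix into a specificity class.

    ``matrix`` is indexed by site/gene id with exactly the five tissue
    columns (replicate-averaged RPM or TPM). Returns a Series of
    :class:`SpecificityLabel`, one per id. Rows above the detection
    threshold must have all 10 tissue pairs in ``diffs``; a missing
    pair raises an error naming the id.
    """
    if set(matrix.columns) != set(TISSUES):
        raise ValueError(f"matrix columns must be exactly {TISSUES}")
    if (matrix.values < 0).any():
        raise ValueError("signal values must be non-negative")
    matrix = matrix[list(TISSUES)]
    labels = {}
    for id_, vals in matrix.iterrows():
        if (vals < detect_threshold).all():
            labels[id_] = SpecificityLabel("unclassified")
            continue

        def sig(a: str, b: str, _id=id_) -> bool:
            fc, padj = diffs.lookup(_id, a, b)
            return fc > fc_threshold and padj < padj_threshold

        labels[id_] = _classify_one(vals, sig, detect_threshold, fc_threshold)
    return pd.Series(labels, name="label")


def classify_genes(
    matrix: pd.DataFrame,
    diffs: DiffTable,
    detect_threshold: float = 5.0,
    fc_threshold: float = 3.0,
    padj_threshold: float = 0.01,
) -> pd.Series:
    """Classify genes from a TPM matrix; same rules as sites at 5 TPM."""
    return classify(matrix, diffs, detect_threshold, fc_threshold, padj_threshold)


def cv_groups(
    expression: pd.DataFrame,
    low_q: float = 0.2,
    high_q: float = 0.2,
) -> pd.Series:
    """Group genes by expression coefficient of variation.

    CV = sd/mean across samples (rows = genes, columns = samples). The
    ``low_q`` fraction with the lowest CVs are labelled ``broad``
    (stably, broadly expressed), the ``high_q`` fraction with the
    highest CVs ``regulated``, the rest ``middle``. Counts are exact
    (floor(n * q)); ties at the boundary are broken by stable gene-id
    order. Zero-mean genes have undefined CV and are excluded (flagged).
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 samples per gene to compute a CV")
    means = expression.mean(axis=1)
    zero = means == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} zero-mean gene(s) with undefined CV",
            stacklevel=2,
        )
    expr = expression.loc[~zero]
    cv = expr.std(axis=1, ddof=1) / means.loc[~zero]
    order = np.argsort(cv.to_numpy(), kind="stable")
    genes = cv.index.to_numpy()[order]
    n = len(genes)
    n_low = int(np.floor(n * low_q))
    n_high = int(np.floor(n * high_q))
    groups = pd.Series("middle", index=cv.index, name="cv_group")
    groups[genes[:n_low]] = "broad"
    if n_high:
        groups[genes[n - n_high:]] = "regulated"
    return groups


def filter_operon_genes(
    ids: pd.Index | list[str],
    operons: pd.DataFrame,
) -> list[str]:
    """Keep non-operon genes and first genes in operons.

    ``operons`` has columns ``gene`` and ``position`` (1-based rank of
    the gene within its operon). Downstream operon genes share their
    operon's promoter via trans-splicing, so only the first gene
    reflects promoter activity.
    """
    if not {"gene", "position"} <= set(operons.columns):
        raise ValueError("operon table needs 'gene' and 'position' columns")
    downstream = set(operons.loc[operons["position"].astype(int) > 1, "gene"])
    return [i for i in ids if i not in downstream]


def read_signal_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV signal matrix (first column = id, tissue columns)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_labels(labels: pd.Series, path: str | Path) -> None:
    out = pd.DataFrame({"id": labels.index, "label": [str(l) for l in labels]})
    out.to_csv(path, sep="\t", index=False)
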
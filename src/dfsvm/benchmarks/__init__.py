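"""Published benchmark score tables used by the comparison statistics.

The CSVs transcribe reported mean scores of ten imbalanced-classification
methods (SMOTE variants, fuzzy-SVM variants, and the deep-feature fuzzy SVM
"DFSVM") on twelve KEEL imbalanced benchmark datasets, one table per metric,
plus a small FSVM-vs-SVM base-classifier ablation table on five of those
datasets.  They are inputs to the rank-based Friedman/Nemenyi comparison,
not outputs of this package.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_benchmark_table", "load_classifier_ablation", "METRICS"]

METRICS = ("gmean", "fmeasure", "auc")


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, index_col="dataset")


def load_benchmark_table(metric: str = "gmean") -> pd.DataFrame:
    """12 datasets x 10 methods mean-score table for one metric."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    return _read(f"{metric}.csv")


def load_classifier_ablation() -> pd.DataFrame:
    """FSVM-vs-SVM base-classifier mean scores on five benchmark datasets."""
    return _read("classifier_ablation.csv")
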
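"""Path -> two-year-outcome analytics and prediction.

Two complementary routes from treatment paths to the two-year outcome
cluster are provided:

* **Empirical** — the path-by-outcome contingency table
  (:class:`PathOutcomeTable`).  A path predicts its modal outcome cluster;
  *concordance* of a path is the fraction of its patients in that modal
  cluster, and *coverage* is the fraction of included patients lying on
  paths large enough (default >= 3 patients) to support a prediction.
* **Model-based** — a multinomial logistic regression of the outcome
  cluster on the path, fitted by maximum likelihood
  (:class:`PathOutcomeModel`).  Either the three components PO, EP, F enter
  as nominal main-effect factors (default), or the full path is a single
  saturated factor.  Significance of the association is judged by the
  likelihood-ratio statistic 2(l_full - l_null) against a chi-square
  reference; for the saturated encoding this statistic coincides with the
  contingency G-statistic of the path-by-outcome table.

With complete separation (some path's patients all in one outcome class)
the multinomial MLE lies on the boundary; results are then reported from
the likelihood supremum (empirical cell proportions, 0*ln 0 = 0) and
flagged via ``separation`` rather than raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError
from .paths import TreatmentPath

__all__ = [
    "PathOutcomeTable",
    "LRTestResult",
    "PathPrediction",
    "PathOutcomeModel",
    "PathOutcomeResults",
    "path_outcome_table",
    "concordance",
    "predict_outcome",
]


@dataclass(frozen=True)
class LRTestResult:
    """Likelihood-ratio test of a fitted model against the intercept-only model."""

    chi_square: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.chi_square < -1e-8:
            raise ValueError("negative LR statistic")
        if self.df < 1:
            raise ValueError("df must be >= 1")

    def __str__(self) -> str:
        return f"LR chi2 = {self.chi_square:.4f}, df = {self.df}, p = {self.p_value:.4g}"


@dataclass(frozen=True)
class PathPrediction:
    """Predicted two-year cluster for one treatment path."""

    path: TreatmentPath
    outcome: int | None  # None: path unseen, no empirical prediction possible
    n: int = 0
    majority_fraction: float | None = None
    ambiguous: bool = False

    @property
    def has_data(self) -> bool:
        return self.outcome is not None


class PathOutcomeTable:
    """Cross-tabulation of treatment paths (rows) by two-year clusters (columns).

    Cells are nonnegative integer counts; the grand total equals the number
    of included patients.
    """

    def __init__(self, frame: pd.DataFrame, paths: Sequence[TreatmentPath]):
        if (frame.to_numpy() < 0).any():
            raise ValidationError("negative count in path-outcome table")
        self._frame = frame
        self._paths = list(paths)
        self._by_key = {str(p): i for i, p in enumerate(self._paths)}

    # ---- constructors -------------------------------------------------
    @classmethod
    def from_labels(
        cls,
        paths: Mapping[str, TreatmentPath],
        y2_labels: Mapping[str, int],
    ) -> "PathOutcomeTable":
        """Exact cross-tabulation of per-patient paths against 2Y labels."""
        missing = sorted(set(paths) - set(y2_labels))
        if missing:
            raise ValidationError(f"patients without 2Y label: {missing}")
        extra = sorted(set(y2_labels) - set(paths))
        if extra:
            raise ValidationError(f"2Y labels for patients without a path: {extra}")
        uniq_paths = sorted(
            {p for p in paths.values()},
            key=lambda p: (p.po_cluster, p.ep_cluster, p.fusion_groups),
        )
        levels = sorted({int(v) for v in y2_labels.values()})
        counts = np.zeros((len(uniq_paths), len(levels)), dtype=int)
        p_index = {p: i for i, p in enumerate(uniq_paths)}
        c_index = {c: j for j, c in enumerate(levels)}
        for pid, path in paths.items():
            counts[p_index[path], c_index[int(y2_labels[pid])]] += 1
        return cls.from_counts(uniq_paths, counts, outcome_levels=levels)

    @classmethod
    def from_counts(
        cls,
        paths: Sequence[TreatmentPath],
        counts: Sequence[Sequence[int]],
        outcome_levels: Sequence[int] | None = None,
    ) -> "PathOutcomeTable":
        counts = np.asarray(counts, dtype=int)
        if outcome_levels is None:
            outcome_levels = list(range(1, counts.shape[1] + 1))
        frame = pd.DataFrame(
            counts,
            index=[str(p) for p in paths],
            columns=[f"2Y{c}" for c in outcome_levels],
        )
        obj = cls.__new__(cls)
        PathOutcomeTable.__init__(obj, frame, paths)
        obj._levels = tuple(int(c) for c in outcome_levels)
        return obj

    # ---- basic accessors ----------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def paths(self) -> list[TreatmentPath]:
        return list(self._paths)

    @property
    def outcome_levels(self) -> tuple[int, ...]:
        return self._levels

    @property
    def counts(self) -> np.ndarray:
        return self._frame.to_numpy(dtype=int)

    @property
    def n_paths(self) -> int:
        return len(self._paths)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def rows(self):
        """Yield (TreatmentPath, counts row) pairs."""
        counts = self.counts
        for i, p in enumerate(self._paths):
            yield p, counts[i]

    def row(self, path: TreatmentPath | str) -> np.ndarray:
        key = str(path)
        if key not in self._by_key:
            raise KeyError(key)
        return self.counts[self._by_key[key]]

    # ---- analytics -----------------------------------------------------
    def concordance(self, min_path_n: int = 3) -> pd.DataFrame:
        """Per-path modal outcome and majority fraction for qualifying paths.

        A path qualifies when its row sum is at least ``min_path_n``.
        Columns: path, n, majority_outcome, majority_fraction,
        majority_percent (integer-rounded, as conventionally reported).
        """
        records = []
        for path, counts in self.rows():
            n = int(counts.sum())
            if n < min_path_n or n == 0:
                continue
            j = int(np.argmax(counts))  # argmax takes the lower index on ties
            frac = counts[j] / n
            records.append(
                {
                    "path": str(path),
                    "n": n,
                    "majority_outcome": self._levels[j],
                    "majority_fraction": frac,
                    "majority_percent": int(round(frac * 100)),
                }
            )
        return pd.DataFrame(
            records,
            columns=["path", "n", "majority_outcome", "majority_fraction", "majority_percent"],
        )

    def coverage(self, min_path_n: int = 3) -> float:
        """Fraction of all included patients on paths with >= min_path_n patients."""
        total = self.grand_total
        if total == 0:
            return 0.0
        qualifying = int(self.row_sums()[self.row_sums() >= min_path_n].sum())
        return qualifying / total

    def predict(self, path: TreatmentPath | str) -> PathPrediction:
        """Empirical prediction: the modal 2Y cluster of the path.

        Unseen paths yield an explicit no-data result; modal ties are
        flagged ambiguous and resolved toward the lower cluster index.
        """
        if isinstance(path, str):
            key = path
            path_obj = self._paths[self._by_key[key]] if key in self._by_key else None
        else:
            key, path_obj = str(path), path
        if key not in self._by_key or self.row(key).sum() == 0:
            return PathPrediction(path=path_obj or path, outcome=None)
        counts = self.row(key)
        j = int(np.argmax(counts))
        ties = int(np.sum(counts == counts[j]))
        n = int(counts.sum())
        return PathPrediction(
            path=self._paths[self._by_key[key]],
            outcome=self._levels[j],
            n=n,
            majority_fraction=counts[j] / n,
            ambiguous=ties > 1,
        )


def path_outcome_table(
    paths: Mapping[str, TreatmentPath], y2_labels: Mapping[str, int]
) -> PathOutcomeTable:
    """Functional alias for :meth:`PathOutcomeTable.from_labels`."""
    return PathOutcomeTable.from_labels(paths, y2_labels)


def concordance(table: PathOutcomeTable, min_path_n: int = 3) -> tuple[pd.DataFrame, float]:
    """Per-path majority fractions and overall coverage."""
    return table.concordance(min_path_n), table.coverage(min_path_n)


def predict_outcome(
    path: TreatmentPath | str, table: PathOutcomeTable
) -> PathPrediction:
    """Functional alias for :meth:`PathOutcomeTable.predict`."""
    return table.predict(path)


# ---------------------------------------------------------------------------
# multinomial logistic regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathOutcomeResults:
    """Fitted multinomial path->outcome regression.

    ``probabilities`` are the fitted per-patient outcome probabilities
    (rows sum to 1); ``lr_test`` compares the fitted model with the
    intercept-only model.  ``separation`` marks (quasi-)complete separation,
    in which case the log-likelihood is the boundary supremum.
    """

    encoding: str
    outcome_levels: tuple[int, ...]
    llf: float
    llnull: float
    lr_test: LRTestResult
    probabilities: np.ndarray
    design_info: tuple[str, ...]
    separation: bool = False
    converged: bool = True
    params: pd.DataFrame | None = None
    _predict_table: PathOutcomeTable | None = None

    def predict(self, path: TreatmentPath | str) -> PathPrediction:
        """Argmax-probability prediction for a path seen in training."""
        if self._predict_table is None:
            raise ValueError("prediction table unavailable")
        key = str(path)
        probs = self._path_probs.get(key)
        if probs is None:
            return PathPrediction(path=path, outcome=None)
        j = int(np.argmax(probs))
        ties = int(np.sum(np.isclose(probs, probs[j], atol=1e-12)))
        return PathPrediction(
            path=path,
            outcome=self.outcome_levels[j],
            n=int(self._predict_table.row(key).sum()),
            majority_fraction=float(probs[j]),
            ambiguous=ties > 1,
        )

    @property
    def _path_probs(self) -> dict[str, np.ndarray]:
        return self.__dict__.setdefault("_path_probs_cache", {})

    def summary(self) -> str:
        lines = [
            f"Multinomial path->outcome model ({self.encoding} encoding)",
            f"  outcome levels: {list(self.outcome_levels)}",
            f"  log-likelihood = {self.llf:.4f} (null {self.llnull:.4f})",
            f"  {self.lr_test}",
        ]
        if self.separation:
            lines.append("  WARNING: complete/quasi-complete separation; "
                         "log-likelihood is the boundary supremum")
        return "\n".join(lines)


class PathOutcomeModel:
    """Multinomial logistic regression of the 2Y cluster on the treatment path.

    Parameters
    ----------
    po, ep, fusion : int sequences
        Path components per patient (cluster and group indices).
    y2 : int sequence
        Observed two-year outcome cluster per patient.
    """

    def __init__(
        self,
        po: Sequence[int],
        ep: Sequence[int],
        fusion: Sequence[int],
        y2: Sequence[int],
    ):
        self.po = np.asarray(po, dtype=int)
        self.ep = np.asarray(ep, dtype=int)
        self.fusion = np.asarray(fusion, dtype=int)
        self.y2 = np.asarray(y2, dtype=int)
        n = len(self.y2)
        if not (len(self.po) == len(self.ep) == len(self.fusion) == n):
            raise ValidationError("po/ep/fusion/y2 must have equal lengths")
        self.outcome_levels = tuple(sorted(np.unique(self.y2)))
        if len(self.outcome_levels) < 2:
            raise ValidationError("need at least two observed outcome categories")

    @classmethod
    def from_paths(
        cls,
        paths: Mapping[str, TreatmentPath],
        y2_labels: Mapping[str, int],
    ) -> "PathOutcomeModel":
        pids = sorted(paths)
        missing = [p for p in pids if p not in y2_labels]
        if missing:
            raise ValidationError(f"patients without 2Y label: {missing}")
        return cls(
            po=[paths[p].po_cluster for p in pids],
            ep=[paths[p].ep_cluster for p in pids],
            fusion=[paths[p].fusion_group for p in pids],
            y2=[y2_labels[p] for p in pids],
        )

    # ------------------------------------------------------------------
    def _design(self, encoding: str) -> tuple[pd.DataFrame, tuple[str, ...]]:
        if encoding == "main_effects":
            df = pd.DataFrame({"PO": self.po, "EP": self.ep, "F": self.fusion})
            X = pd.get_dummies(
                df.astype("category"), drop_first=True, dtype=float
            )
        elif encoding == "saturated":
            key = pd.Series(
                [f"PO{a}-EP{b}-F{c}" for a, b, c in zip(self.po, self.ep, self.fusion)]
            )
            X = pd.get_dummies(key.astype("category"), drop_first=True, dtype=float)
        else:
            raise ValueError(f"unknown encoding {encoding!r}")
        X.insert(0, "const", 1.0)
        return X, tuple(X.columns)

    def fit(
        self,
        encoding: str = "main_effects",
        ridge: float = 0.0,
        maxiter: int = 500,
    ) -> PathOutcomeResults:
        """Fit by maximum likelihood (statsmodels MNLogit under the hood).

        ``encoding='main_effects'`` uses PO, EP and F as nominal factors;
        ``'saturated'`` uses one indicator per observed path.  A positive
        ``ridge`` adds an L2 penalty (useful under separation; clearly a
        different estimator, so off by default).
        """
        X, names = self._design(encoding)
        levels = self.outcome_levels
        y_codes = np.searchsorted(levels, self.y2)
        K = len(levels)

        separation = self._detect_separation()
        params = None
        if ridge > 0:
            # penalized estimator for separated data; clearly not the MLE
            from sklearn.linear_model import LogisticRegression

            lr_model = LogisticRegression(
                C=1.0 / ridge, max_iter=maxiter, solver="lbfgs"
            ).fit(X.to_numpy()[:, 1:], y_codes)  # sklearn adds its own intercept
            probs = lr_model.predict_proba(X.to_numpy()[:, 1:])
            llf = float(np.sum(np.log(probs[np.arange(len(y_codes)), y_codes])))
            converged = True
        elif encoding == "saturated" and separation:
            # MLE is on the boundary; report the likelihood supremum
            # (the limit of the MLE path), flagged via `separation`
            llf, probs = self._boundary_llf()
            converged = False
        else:
            import statsmodels.api as sm

            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.MNLogit(y_codes, X.to_numpy()).fit(
                        method="newton", maxiter=maxiter, disp=0
                    )
                converged = bool(fit.mle_retvals.get("converged", True))
                llf = float(fit.llf)
                probs = np.asarray(fit.predict(X.to_numpy()))
                if not (np.isfinite(llf) and np.all(np.isfinite(probs))):
                    raise np.linalg.LinAlgError("Newton fit diverged")
                params = pd.DataFrame(
                    fit.params,
                    index=names,
                    columns=[f"2Y{levels[j + 1]}" for j in range(K - 1)],
                )
            except np.linalg.LinAlgError:
                # Newton fails when separation drives coefficients to
                # infinity (singular Hessian or NaN likelihood): take the
                # quasi-Newton estimate instead of crashing, and flag it
                from sklearn.linear_model import LogisticRegression

                lr_model = LogisticRegression(
                    C=np.inf, max_iter=max(maxiter, 2000), solver="lbfgs"
                ).fit(X.to_numpy()[:, 1:], y_codes)
                probs = lr_model.predict_proba(X.to_numpy()[:, 1:])
                llf = float(np.sum(np.log(probs[np.arange(len(y_codes)), y_codes])))
                converged = False
                separation = True

        llnull = self._null_llf(y_codes, K)
        df = (len(names) - 1) * (K - 1)
        chi2 = max(0.0, 2.0 * (llf - llnull))
        lr = LRTestResult(
            chi_square=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df))
        )
        res = PathOutcomeResults(
            encoding=encoding,
            outcome_levels=levels,
            llf=llf,
            llnull=llnull,
            lr_test=lr,
            probabilities=probs,
            design_info=names,
            separation=separation,
            converged=converged,
            params=params,
            _predict_table=self._table(),
        )
        # cache per-path fitted probabilities for prediction
        keys = [
            str(TreatmentPath(a, b, (c,)))
            for a, b, c in zip(self.po, self.ep, self.fusion)
        ]
        for key, p in zip(keys, probs):
            res._path_probs.setdefault(key, np.asarray(p, dtype=float))
        return res

    # ------------------------------------------------------------------
    def _table(self) -> PathOutcomeTable:
        paths = {
            f"p{i:04d}": TreatmentPath(a, b, (c,))
            for i, (a, b, c) in enumerate(zip(self.po, self.ep, self.fusion))
        }
        y2 = {f"p{i:04d}": int(v) for i, v in enumerate(self.y2)}
        return PathOutcomeTable.from_labels(paths, y2)

    def _detect_separation(self) -> bool:
        # a path with any empty outcome cell puts part of the saturated MLE
        # on the boundary (coefficients diverging to -inf)
        counts = self._table().counts
        return bool(np.any(counts == 0))

    def _boundary_llf(self) -> tuple[float, np.ndarray]:
        table = self._table()
        counts = table.counts.astype(float)
        row_p = counts / counts.sum(axis=1, keepdims=True)
        key_of = {str(p): i for i, p in enumerate(table.paths)}
        keys = [
            str(TreatmentPath(a, b, (c,)))
            for a, b, c in zip(self.po, self.ep, self.fusion)
        ]
        probs = np.stack([row_p[key_of[k]] for k in keys])
        with np.errstate(divide="ignore"):
            ll = counts * np.log(np.where(counts > 0, row_p, 1.0))
        return float(ll.sum()), probs

    def _null_llf(self, y_codes: np.ndarray, K: int) -> float:
        counts = np.bincount(y_codes, minlength=K).astype(float)
        p = counts / counts.sum()
        with np.errstate(divide="ignore"):
            return float(np.sum(counts[counts > 0] * np.log(p[counts > 0])))


def fit_multinomial(
    po: Sequence[int],
    ep: Sequence[int],
    fusion: Sequence[int],
    y2: Sequence[int],
    encoding: str = "main_effects",
) -> tuple[PathOutcomeResults, LRTestResult]:
    """Fit the path->outcome multinomial model; returns (results, LR test)."""
    res = PathOutcomeModel(po, ep, fusion, y2).fit(encoding=encoding)
    return res, res.lr_test
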
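"""Model terms, design matrices, and the fitted-model container."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

Z95 = 1.959963984540054


def term_matrix(data, terms) -> np.ndarray:
    """Design matrix for a list of terms over scaled covariate columns.

    A term is a covariate name or an interaction ``"a:b"`` (elementwise
    product of the scaled columns).  ``data`` is a DataFrame or a dict of
    equal-length arrays.
    """
    cols = []
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            cols.append(np.asarray(data[a], dtype=float) * np.asarray(data[b], dtype=float))
        else:
            cols.append(np.asarray(data[term], dtype=float))
    return np.column_stack(cols) if cols else np.empty((_length(data), 0))


def _length(data) -> int:
    if isinstance(data, pd.DataFrame):
        return len(data)
    return len(next(iter(data.values())))


def base_covariates(terms) -> list:
    """Unique base covariate names appearing in a term list, in order."""
    seen: dict = {}
    for term in terms:
        for part in term.split(":"):
            seen.setdefault(part, None)
    return list(seen)


@dataclass
class ModelFit:
    """Fixed effects with Wald inference, random-effect variances, fit stats."""

    terms: list
    estimates: dict  # term -> coefficient
    se: dict  # term -> standard error
    loglik: float
    n_obs: int
    converged: bool = True
    random_effects: dict = field(default_factory=dict)  # name -> {variance, fixed}
    flags: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        """Estimated parameters: fixed effects + free random-effect variances."""
        free_var = sum(1 for re in self.random_effects.values() if not re.get("fixed", False))
        return len(self.terms) + free_var

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def z(self, term: str) -> float:
        return self.estimates[term] / self.se[term]

    def ci95(self, term: str) -> tuple:
        est, se = self.estimates[term], self.se[term]
        return (est - Z95 * se, est + Z95 * se)

    def beta_vector(self) -> np.ndarray:
        return np.array([self.estimates[t] for t in self.terms])

    def se_vector(self) -> np.ndarray:
        return np.array([self.se[t] for t in self.terms])

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            lo, hi = self.ci95(t)
            rows.append({"term": t, "estimate": self.estimates[t], "se": self.se[t], "z": self.z(t), "ci_lo": lo, "ci_hi": hi})
        return pd.DataFrame(rows)

    # -- serialization ------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["aic"] = self.aic
        payload["vcov"] = self.extra.get("vcov")
        txt = json.dumps(_jsonable(payload), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(txt)
        return txt

    @classmethod
    def from_json(cls, source) -> "ModelFit":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        payload.pop("aic", None)
        payload.pop("vcov", None)
        return cls(**payload)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
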
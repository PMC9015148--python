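"""Logistic combination of shape and electrostatic similarity into Surf_S.

The default weights are the fitted values

    Surf_S = 1 / (1 + exp(13.79986756 - 14.64347448*S_S + 13.78594078*E_S))

obtained from a logistic regression of native vs. non-native interface
substitutions (one native and eighteen non-native point mutations per
complex).  :func:`fit_weights` refits the same model from labeled
(S_S, E_S) records with plain maximum likelihood (no regularization) and
reports held-out accuracy at threshold 0.5.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WeightSet", "DEFAULT_WEIGHTS", "surf_score", "fit_weights",
           "rank_candidates", "LabeledScoreRecord", "read_records",
           "write_records"]


@dataclass(frozen=True)
class WeightSet:
    """Intercept and coefficients of the Surf_S logistic model, in the
    convention Surf_S = 1/(1 + exp(b0 + b_ss*S_S + b_es*E_S))."""
    b0: float
    b_ss: float
    b_es: float

    def to_json(self) -> str:
        return json.dumps({"b0": self.b0, "b_ss": self.b_ss,
                           "b_es": self.b_es})

    @classmethod
    def from_json(cls, text: str) -> "WeightSet":
        d = json.loads(text)
        return cls(d["b0"], d["b_ss"], d["b_es"])


DEFAULT_WEIGHTS = WeightSet(b0=13.79986756, b_ss=-14.64347448,
                            b_es=13.78594078)


def surf_score(s_s: float, e_s: float,
               weights: WeightSet = DEFAULT_WEIGHTS) -> float:
    """Combined surface similarity Surf_S in (0, 1); 1 = highly similar."""
    z = weights.b0 + weights.b_ss * s_s + weights.b_es * e_s
    return float(1.0 / (1.0 + np.exp(z)))


@dataclass
class LabeledScoreRecord:
    s_s: float
    e_s: float
    is_native: bool
    complex_id: str = ""
    residue_type: str = ""


def write_records(records: list[LabeledScoreRecord], path) -> None:
    pd.DataFrame(
        [{"complex_id": r.complex_id, "residue_type": r.residue_type,
          "s_s": r.s_s, "e_s": r.e_s, "is_native": int(r.is_native)}
         for r in records]).to_csv(path, sep="\t", index=False)


def read_records(path) -> list[LabeledScoreRecord]:
    df = pd.read_csv(path, sep="\t")
    return [LabeledScoreRecord(s_s=row.s_s, e_s=row.e_s,
                               is_native=bool(row.is_native),
                               complex_id=str(row.complex_id),
                               residue_type=str(row.residue_type))
            for row in df.itertuples(index=False)]


def fit_weights(records: list[LabeledScoreRecord],
                test_fraction: float = 0.2, seed: int = 0
                ) -> tuple[WeightSet, float]:
    """Maximum-likelihood logistic regression of is_native on (S_S, E_S).

    Returns the fitted weights in the same sign convention as
    :data:`DEFAULT_WEIGHTS` plus accuracy at threshold 0.5 on a held-out
    split of ``test_fraction`` of the records.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    if len(records) < 10:
        raise ValueError("fewer than 10 records")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    x = np.array([[r.s_s, r.e_s] for r in records])
    y = np.array([r.is_native for r in records], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class data")
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_fraction, random_state=seed, stratify=y)
    # C=inf => plain maximum likelihood, no regularization
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10000,
                             tol=1e-10)
    clf.fit(x_tr, y_tr)
    accuracy = float((clf.predict(x_te) == y_te).mean())
    # sklearn: P(native) = 1/(1+exp(-(c0 + c.x))); our convention negates
    ws = WeightSet(b0=-float(clf.intercept_[0]),
                   b_ss=-float(clf.coef_[0][0]),
                   b_es=-float(clf.coef_[0][1]))
    return ws, accuracy


def rank_candidates(scores: dict[str, float], tie_tolerance: float = 1e-9
                    ) -> tuple[list[tuple[str, float]], bool]:
    """Rank candidate residues by score, descending.

    Returns the ordered (residue, score) list and a ``unique_best`` flag
    that is True only when the top score exceeds the runner-up by more than
    ``tie_tolerance`` — the operational meaning of a uniquely identifiable
    native residue.
    """
    if not scores:
        raise ValueError("empty candidate set")
    if len(scores) < 2:
        raise ValueError("need at least 2 candidates")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    unique_best = (ordered[0][1] - ordered[1][1]) > tie_tolerance
    return ordered, unique_best
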
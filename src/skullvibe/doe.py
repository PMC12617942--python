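"""Two-level full factorial sensitivity studies.

Material parameters (factors) are varied between a low and a high
physical value, coded -1/+1; every sign combination is one run.  The
response of each run is a scalar — in the material studies, the median
FRFSM similarity between model and reference across the sensor array.
Main effects and two-factor interactions are estimated with the
standard orthogonal contrasts:

    main effect of factor i = mean(y | x_i = +1) - mean(y | x_i = -1)
    interaction(i, j)       = 2 * mean(y * x_i * x_j)

so a noiseless response b0 + sum b_i x_i + sum b_ij x_i x_j is
recovered exactly as effects 2*b_i and interactions 2*b_ij.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FactorialDesign:
    """A 2^f full factorial design with +-1 coding.

    ``matrix`` has one row per run in deterministic order (binary
    counting with the first factor fastest); ``lows``/``highs`` give
    the physical values behind the codes.
    """

    names: list
    lows: np.ndarray
    highs: np.ndarray
    matrix: np.ndarray  # (2^f, f) of -1/+1

    @property
    def n_runs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_factors(self) -> int:
        return self.matrix.shape[1]

    def physical_values(self, run: int) -> dict:
        """Map one coded run to factor-name -> physical value."""
        row = self.matrix[run]
        vals = np.where(row > 0, self.highs, self.lows)
        return dict(zip(self.names, vals.tolist()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.names)
        df.insert(0, "run", np.arange(self.n_runs))
        return df


def full_factorial(factors: list) -> FactorialDesign:
    """All 2^f combinations of (name, low, high) factor levels.

    Runs are ordered by binary counting with the *first* factor
    alternating fastest; run 0 is all-low.
    """
    if not 1 <= len(factors) <= 12:
        raise ValueError(f"need between 1 and 12 factors, got {len(factors)}")
    names = [f[0] for f in factors]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate factor names: {dupes}")
    f = len(factors)
    runs = np.arange(2**f)
    matrix = np.where((runs[:, None] >> np.arange(f)[None, :]) & 1, 1, -1)
    return FactorialDesign(
        names,
        np.array([x[1] for x in factors], float),
        np.array([x[2] for x in factors], float),
        matrix.astype(np.int8),
    )


@dataclass
class StudyResult:
    """Responses plus effect estimates of one factorial study."""

    design: FactorialDesign
    responses: np.ndarray  # (n_runs,), NaN for failed runs
    failures: list  # (run index, error message)
    main_effects: dict | None = None
    interactions: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.design.to_frame()
        df["response"] = self.responses
        return df


def run_study(design: FactorialDesign, evaluator) -> StudyResult:
    """Evaluate every run of the design.

    ``evaluator`` maps a dict of physical factor values to a scalar
    response.  A failing run is recorded (NaN response) and the study
    continues; effects are computed only if every run succeeded.
    """
    responses = np.full(design.n_runs, np.nan)
    failures = []
    for run in range(design.n_runs):
        try:
            responses[run] = float(evaluator(design.physical_values(run)))
        except Exception as err:  # noqa: BLE001 - study must survive bad runs
            failures.append((run, f"{type(err).__name__}: {err}"))
    result = StudyResult(design, responses, failures)
    if not failures:
        result.main_effects, result.interactions = effects(design, responses)
    return result


def effects(design: FactorialDesign, responses):
    """Main effects and two-factor interactions from complete responses.

    Returns (main, inter): ``main`` maps factor name to its effect,
    ``inter`` maps (name_i, name_j) with i < j to the interaction.
    """
    y = np.asarray(responses, float).ravel()
    if y.shape[0] != design.n_runs:
        raise ValueError(f"expected {design.n_runs} responses, got {y.shape[0]}")
    missing = np.flatnonzero(~np.isfinite(y))
    if missing.size:
        raise ValueError(f"missing/failed runs: {missing.tolist()}")
    X = design.matrix.astype(float)
    main = {name: float(np.mean(y[X[:, i] > 0]) - np.mean(y[X[:, i] < 0]))
            for i, name in enumerate(design.names)}
    inter = {}
    for i in range(design.n_factors):
        for j in range(i + 1, design.n_factors):
            inter[(design.names[i], design.names[j])] = float(
                2.0 * np.mean(y * X[:, i] * X[:, j]))
    return main, inter
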
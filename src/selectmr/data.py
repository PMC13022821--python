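"""Data containers for selection-model and Mendelian randomization analyses.

A :class:`SelectionDataset` holds the ingredients of a sample-selection
regression: an outcome design matrix ``X`` (with intercept), a selection
design matrix ``X~`` that must additionally contain at least one instrument
for selection ``Z`` excluded from the outcome design, the (partially
observed) outcome, and the binary selection indicator ``R``.

An :class:`MRDataset` holds individual-level Mendelian randomization data:
genetic instruments ``G``, exposure ``X`` and outcome ``Y`` (either of which
may be masked for non-selected individuals), the instrument for selection
``Z`` (observed for everyone), and the selection indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _as_matrix(a, name):
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {a.shape}")
    return a


@dataclass
class SelectionDataset:
    """Rectangular data for a sample-selection regression.

    Parameters
    ----------
    outcome_design : (n, p) array
        Design matrix of the outcome regression, including the intercept
        column.
    selection_design : (n, q) array
        Design matrix of the selection model, including the intercept and at
        least one instrument-for-selection column not present in
        ``outcome_design``.
    outcome : (n,) array
        Outcome values; entries for non-selected individuals may be NaN.
    selected : (n,) array of {0, 1}
        Selection indicator R; 1 where the outcome is observed.
    """

    outcome_design: np.ndarray
    selection_design: np.ndarray
    outcome: np.ndarray
    selected: np.ndarray
    outcome_names: list = field(default=None)
    selection_names: list = field(default=None)

    def __post_init__(self):
        self.outcome_design = _as_matrix(self.outcome_design, "outcome_design")
        self.selection_design = _as_matrix(self.selection_design, "selection_design")
        self.outcome = np.asarray(self.outcome, dtype=float).ravel()
        self.selected = np.asarray(self.selected).ravel().astype(bool)
        n = self.outcome_design.shape[0]
        if not (self.selection_design.shape[0] == self.outcome.size == self.selected.size == n):
            raise ValueError("all components must share the same number of rows")
        if n < self.n_outcome_params + self.n_selection_params:
            raise ValueError("fewer rows than parameters")
        if np.any(~np.isfinite(self.outcome[self.selected])):
            raise ValueError("outcome must be observed (finite) for every selected row")
        if self.outcome_names is None:
            self.outcome_names = [f"x{j}" for j in range(self.outcome_design.shape[1])]
        if self.selection_names is None:
            self.selection_names = [f"w{j}" for j in range(self.selection_design.shape[1])]

    @property
    def nobs(self) -> int:
        return self.outcome_design.shape[0]

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def n_outcome_params(self) -> int:
        return self.outcome_design.shape[1]

    @property
    def n_selection_params(self) -> int:
        return self.selection_design.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, covariates,
                       selection_instruments, selected: str | None = None):
        """Build a dataset from a tidy data frame.

        ``covariates`` enter both designs; ``selection_instruments`` enter
        only the selection design. An intercept is prepended to both designs.
        If ``selected`` is None the indicator is derived from outcome
        missingness.
        """
        covariates = list(covariates)
        selection_instruments = list(selection_instruments)
        z = df[selection_instruments].to_numpy(dtype=float)
        if np.any(~np.isfinite(z)):
            raise ValueError(
                "instrument-for-selection column(s) contain missing values; "
                "Z must be observed for all individuals"
            )
        y = df[outcome].to_numpy(dtype=float)
        r = df[selected].to_numpy() if selected is not None else np.isfinite(y)
        n = len(df)
        ones = np.ones((n, 1))
        xmat = df[covariates].to_numpy(dtype=float) if covariates else np.empty((n, 0))
        return cls(
            outcome_design=np.hstack([ones, xmat]),
            selection_design=np.hstack([ones, xmat, z]),
            outcome=y,
            selected=r,
            outcome_names=["const"] + covariates,
            selection_names=["const"] + covariates + selection_instruments,
        )


@dataclass
class MRDataset:
    """Individual-level Mendelian randomization data with possible masking.

    ``instruments`` holds the n x K matrix of genetic instruments G (a
    continuous score when K=1, or allele counts). ``exposure`` and
    ``outcome`` may contain NaN for non-selected rows, depending on which
    variable drives selection. ``selection_instrument`` (Z) must be observed
    for every individual.
    """

    instruments: np.ndarray
    exposure: np.ndarray
    outcome: np.ndarray
    selection_instrument: np.ndarray
    selected: np.ndarray

    def __post_init__(self):
        self.instruments = _as_matrix(self.instruments, "instruments")
        self.exposure = np.asarray(self.exposure, dtype=float).ravel()
        self.outcome = np.asarray(self.outcome, dtype=float).ravel()
        self.selection_instrument = np.asarray(self.selection_instrument, dtype=float).ravel()
        self.selected = np.asarray(self.selected).ravel().astype(bool)
        n = self.instruments.shape[0]
        if not (self.exposure.size == self.outcome.size ==
                self.selection_instrument.size == self.selected.size == n):
            raise ValueError("all components must share the same number of rows")
        if np.any(~np.isfinite(self.selection_instrument)):
            raise ValueError("Z must be observed for all individuals in the sample")

    @property
    def nobs(self) -> int:
        return self.instruments.shape[0]

    @property
    def n_instruments(self) -> int:
        return self.instruments.shape[1]

    def exposure_masked(self) -> bool:
        return bool(np.any(~np.isfinite(self.exposure)))

    def outcome_masked(self) -> bool:
        return bool(np.any(~np.isfinite(self.outcome)))

    def selection_dataset(self, side: str) -> SelectionDataset:
        """SelectionDataset for the per-variant / allele-score regression of
        one side (exposure or outcome) on all instruments G, with selection
        design [1, G, Z]."""
        y = self.exposure if side == "exposure" else self.outcome
        n = self.nobs
        ones = np.ones((n, 1))
        return SelectionDataset(
            outcome_design=np.hstack([ones, self.instruments]),
            selection_design=np.hstack([ones, self.instruments,
                                        self.selection_instrument[:, None]]),
            outcome=y,
            selected=self.selected,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, instruments, exposure: str,
                       outcome: str, selection_instrument: str,
                       selected: str | None = None):
        instruments = list(instruments)
        g = df[instruments].to_numpy(dtype=float)
        x = df[exposure].to_numpy(dtype=float)
        y = df[outcome].to_numpy(dtype=float)
        z = df[selection_instrument].to_numpy(dtype=float)
        if selected is not None:
            r = df[selected].to_numpy()
        else:
            r = np.isfinite(x) & np.isfinite(y)
        return cls(instruments=g, exposure=x, outcome=y,
                   selection_instrument=z, selected=r)
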
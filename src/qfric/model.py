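"""The central quantitative link: lambda = zeta * (Delta E_micro)^2.

Across surfaces of different lattice and charge, the Green-Kubo friction
coefficient lambda grows linearly with the variance of the microscopic
energy map, with a single proportionality factor zeta (~130 in units of
N s m^-3 per (kJ/mol)^2 for the lattices studied here, valid while
Delta E_micro stays below ~0.45 kJ/mol).  Because the Coulomb part of the
map is linear in the decoration charge q, both (Delta E_micro)^2 and
lambda scale as q^2.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LambdaE2Dataset",
    "ZetaFit",
    "ScalingFit",
    "fit_zeta",
    "q_scaling_exponent",
]


@dataclass
class LambdaE2Dataset:
    """Paired (q, (Delta E_micro)^2, lambda) records over surfaces."""

    surface_id: np.ndarray
    q: np.ndarray          # e
    var_e: np.ndarray      # (kJ/mol)^2
    lam: np.ndarray        # N s/m^3
    kind: np.ndarray

    def __post_init__(self):
        self.surface_id = np.asarray(self.surface_id)
        self.q = np.asarray(self.q, dtype=float)
        self.var_e = np.asarray(self.var_e, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.kind = np.asarray(self.kind)
        n = len(self.surface_id)
        if not (len(self.q) == len(self.var_e) == len(self.lam)
                == len(self.kind) == n):
            raise ValueError("all dataset columns must have equal length")
        if np.any(self.var_e < 0):
            raise ValueError("(Delta E_micro)^2 must be >= 0")
        if np.any(self.lam < 0):
            raise ValueError("lambda must be >= 0")

    def __len__(self) -> int:
        return len(self.q)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "surface": self.surface_id, "q_e": self.q,
            "varE_kJmol2": self.var_e, "lambda_Nsm3": self.lam,
            "kind": self.kind})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LambdaE2Dataset":
        return cls(df["surface"].to_numpy(), df["q_e"].to_numpy(),
                   df["varE_kJmol2"].to_numpy(),
                   df["lambda_Nsm3"].to_numpy(), df["kind"].to_numpy())

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LambdaE2Dataset":
        return cls.from_frame(pd.read_csv(path, comment="#"))


@dataclass
class ZetaFit:
    """Least-squares slope of lambda on (Delta E_micro)^2."""

    zeta: float            # N s m^-3 per (kJ/mol)^2
    intercept: float       # N s/m^3
    r_squared: float
    n_used: int
    n_excluded: int
    cutoff: float          # kJ/mol, upper bound on Delta E_micro
    through_origin: bool
    excluded_ids: list = field(default_factory=list)


def fit_zeta(data: LambdaE2Dataset, through_origin: bool = True,
             cutoff: float = 0.45) -> ZetaFit:
    """Fit zeta, using only records with Delta E_micro below ``cutoff``.

    The fit is through the origin by default (zero corrugation should
    mean zero Coulomb-driven friction); an intercept can be requested to
    absorb the Lennard-Jones floor.  Note zeta's units are fixed by the
    conventions here - N s m^-3 per (kJ mol^-1)^2 - so numerical values
    are comparable only under the same convention.
    """
    adm = np.sqrt(data.var_e) < cutoff
    x, y = data.var_e[adm], data.lam[adm]
    excluded = [str(s) for s in data.surface_id[~adm]]
    need = 1 if through_origin else 2
    if len(x) < need:
        raise ValueError(
            f"only {len(x)} record(s) below the Delta E_micro cutoff "
            f"{cutoff} kJ/mol; need >= {need}")
    if through_origin:
        denom = float(x @ x)
        if denom == 0:
            raise ValueError("all admissible records have var_E = 0")
        zeta = float(x @ y) / denom
        intercept = 0.0
        ss_res = float(np.sum((y - zeta * x) ** 2))
        ss_tot = float(np.sum(y ** 2))
    else:
        if np.ptp(x) == 0:
            raise ValueError("var_E values are degenerate; slope undetermined")
        zeta, intercept = np.polyfit(x, y, 1)
        ss_res = float(np.sum((y - (zeta * x + intercept)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ZetaFit(float(zeta), float(intercept), float(r2),
                   int(adm.sum()), int((~adm).sum()), cutoff,
                   through_origin, excluded)


@dataclass
class ScalingFit:
    """Log-log power-law exponent with its standard error."""

    exponent: float
    stderr: float
    r_value: float
    n: int


def q_scaling_exponent(data, field_name: str = "var_e",
                       values=None) -> ScalingFit:
    """Power-law exponent of a field against the decoration charge q.

    Call either with a :class:`LambdaE2Dataset` and ``field_name`` in
    {"var_e", "lam"}, or with plain arrays ``(q, values=...)``.  Records
    at q = 0 are skipped with a warning (they cannot enter a log-log
    regression); at least 3 distinct positive q are required.
    """
    if isinstance(data, LambdaE2Dataset):
        q = data.q
        vals = {"var_e": data.var_e, "lam": data.lam}[field_name]
    else:
        q = np.asarray(data, dtype=float)
        vals = np.asarray(values, dtype=float)
    keep = q > 0
    if (~keep).any():
        warnings.warn(f"skipping {int((~keep).sum())} record(s) at q = 0 "
                      "in the log-log regression", stacklevel=2)
    q, vals = q[keep], vals[keep]
    if len(np.unique(q)) < 3:
        raise ValueError("need >= 3 distinct positive q values")
    if np.any(vals <= 0):
        raise ValueError("field values must be positive for a log-log fit")
    res = stats.linregress(np.log(q), np.log(vals))
    stderr = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    rval = 1.0 if np.isnan(res.rvalue) else float(res.rvalue)
    return ScalingFit(float(res.slope), stderr, rval, len(q))
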
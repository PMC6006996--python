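"""Parameter balancing: thermodynamically consistent Bayesian estimation.

All kinetic quantities of a network are expressed as linear functions of a
*basic* quantity vector

    q = (μ°_i | ln kM_{j,i} | ln kV_j | ln u_j | ln c_i)

with μ° the standard chemical potentials (kJ·mol⁻¹, linear scale) and the
rest on the natural-log scale. The dependent quantities follow from

    ln keq_j    = −(1/RT) Σ_i n_ij μ°_i
    ln kcat±_j  = ln kV_j ∓ (h_j/2) Σ_i n_ij (μ°_i/RT + ln kM_{j,i})
    ln vmax±_j  = ln u_j + ln kcat±_j
    μ_i         = μ°_i + RT ln c_i
    Rᴬ_j        = −Δ_jG = −Σ_i n_ij μ_i

where n_ij is the signed stoichiometric coefficient and the kM sums run
over the participants of reaction j. Because every dependent quantity is a
linear map of q, the Haldane relationships and Wegscheider cycle conditions
hold *by construction* for the posterior mean and for every sampled draw.

Measurements enter as Gaussian likelihood rows on the same linear maps and
the posterior is the standard linear-Gaussian update

    Σ_post = (Σ0⁻¹ + Qᵀ Σx⁻¹ Q)⁻¹,   μ_post = Σ_post (Σ0⁻¹ q0 + Qᵀ Σx⁻¹ x)

computed with a symmetric factorisation (never an explicit inverse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .network import Network, stoichiometric_matrix

__all__ = [
    "BalancingConfig",
    "QuantitySystem",
    "GaussianDistribution",
    "BalancedParameters",
    "build_quantity_system",
    "assemble_priors",
    "assemble_measurements",
    "balance",
    "derive_all_quantities",
    "haldane_residuals",
    "wegscheider_residuals",
    "sample_parameters",
    "write_balanced_table",
    "BASIC_QUANTITIES",
    "DEPENDENT_QUANTITIES",
]

BASIC_QUANTITIES = ("mu0", "kM", "kV", "u", "c")
DEPENDENT_QUANTITIES = ("keq", "kcat_forward", "kcat_reverse",
                        "vmax_forward", "vmax_reverse", "mu", "RA")
#: quantities living on a log scale (medians are exp of the posterior mean)
MULTIPLICATIVE = {"kM", "kV", "u", "c", "keq",
                  "kcat_forward", "kcat_reverse", "vmax_forward", "vmax_reverse"}


@dataclass
class BalancingConfig:
    """Constants and pseudo-prior table for the balancing stage.

    The pseudo-priors are broad defaults standing in for unmeasured
    quantities: (median, log-scale std) for the multiplicative quantities
    and (mean kJ·mol⁻¹, std) for μ°.
    """

    R: float = 8.314          # J·mol⁻¹·K⁻¹
    T: float = 300.0          # K
    default_log_std: float = math.log(2.0)  # measurement spread when unstated
    pseudo_priors: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "kM": (0.1, math.log(10.0)),   # mM
        "kV": (10.0, math.log(10.0)),  # s⁻¹
        "u": (0.01, math.log(10.0)),   # mM
        "c": (0.1, math.log(10.0)),    # mM
        # μ° spread approximating experimentally expected standard
        # potentials; keeps pseudo-range keq within exp(±~11)
        "mu0": (0.0, 20.0),            # kJ·mol⁻¹
    })

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError("temperature must be positive")
        for name, (_, std) in self.pseudo_priors.items():
            if not std > 0:
                raise ValueError(f"pseudo-prior std for {name!r} must be positive")

    @property
    def RT(self) -> float:
        """R·T in kJ·mol⁻¹ (the scale on which μ° is stored)."""
        return self.R * self.T / 1000.0


class QuantitySystem:
    """Index of the basic quantity vector and the linear dependency rows."""

    def __init__(self, network: Network, config: Optional[BalancingConfig] = None):
        self.network = network
        self.config = config or BalancingConfig()
        mets = network.metabolite_ids
        rxns = network.reaction_ids
        for rid in rxns:
            if not network.reactions[rid].stoichiometry:
                raise ValueError(f"reaction {rid!r} has no participants")
        self.metabolite_ids = mets
        self.reaction_ids = rxns
        self._met_pos = {m: i for i, m in enumerate(mets)}
        self._rxn_pos = {r: j for j, r in enumerate(rxns)}
        # kM entries: every participant, plus regulator-only pairs (those do
        # not enter the thermodynamic rows but are needed by the rate law)
        self.km_pairs: list[tuple[str, str]] = []
        self._n_participant_kms: dict[str, int] = {}
        for rid in rxns:
            rxn = network.reactions[rid]
            parts = list(rxn.stoichiometry)
            self._n_participant_kms[rid] = len(parts)
            for met in parts:
                self.km_pairs.append((rid, met))
            for reg in rxn.regulators:
                if reg.metabolite_id not in rxn.stoichiometry:
                    self.km_pairs.append((rid, reg.metabolite_id))
        self._km_pos = {pair: k for k, pair in enumerate(self.km_pairs)}
        nm, nr, nk = len(mets), len(rxns), len(self.km_pairs)
        self.off_mu0 = 0
        self.off_km = nm
        self.off_kv = nm + nk
        self.off_u = nm + nk + nr
        self.off_c = nm + nk + 2 * nr
        self.dim = nm + nk + 2 * nr + nm

    # -- basic indices --------------------------------------------------------
    def index(self, quantity: str, reaction_id: Optional[str] = None,
              metabolite_id: Optional[str] = None) -> int:
        if quantity == "mu0":
            return self.off_mu0 + self._met_pos[metabolite_id]
        if quantity == "kM":
            return self.off_km + self._km_pos[(reaction_id, metabolite_id)]
        if quantity == "kV":
            return self.off_kv + self._rxn_pos[reaction_id]
        if quantity == "u":
            return self.off_u + self._rxn_pos[reaction_id]
        if quantity == "c":
            return self.off_c + self._met_pos[metabolite_id]
        raise KeyError(f"{quantity!r} is not a basic quantity")

    def basic_kind(self, k: int) -> tuple[str, Optional[str], Optional[str]]:
        """(quantity, reaction_id, metabolite_id) of basic coordinate k."""
        if k < self.off_km:
            return "mu0", None, self.metabolite_ids[k]
        if k < self.off_kv:
            rid, mid = self.km_pairs[k - self.off_km]
            return "kM", rid, mid
        if k < self.off_u:
            return "kV", self.reaction_ids[k - self.off_kv], None
        if k < self.off_c:
            return "u", self.reaction_ids[k - self.off_u], None
        return "c", None, self.metabolite_ids[k - self.off_c]

    # -- dependency rows ------------------------------------------------------
    def row(self, quantity: str, reaction_id: Optional[str] = None,
            metabolite_id: Optional[str] = None) -> np.ndarray:
        """Linear map over the basic vector defining ``quantity``."""
        RT = self.config.RT
        r = np.zeros(self.dim)
        if quantity in BASIC_QUANTITIES:
            r[self.index(quantity, reaction_id, metabolite_id)] = 1.0
            return r
        if quantity == "mu":
            r[self.index("mu0", metabolite_id=metabolite_id)] = 1.0
            r[self.index("c", metabolite_id=metabolite_id)] = RT
            return r
        rxn = self.network.reactions[reaction_id]
        if quantity == "keq":
            for met, n in rxn.stoichiometry.items():
                r[self.index("mu0", metabolite_id=met)] -= n / RT
            return r
        if quantity == "RA":
            for met, n in rxn.stoichiometry.items():
                r -= n * self.row("mu", metabolite_id=met)
            return r
        if quantity in ("kcat_forward", "kcat_reverse"):
            sign = -1.0 if quantity == "kcat_forward" else 1.0
            h = rxn.cooperativity
            r[self.index("kV", reaction_id=reaction_id)] = 1.0
            for met, n in rxn.stoichiometry.items():
                r[self.index("mu0", metabolite_id=met)] += sign * (h / 2.0) * n / RT
                r[self.index("kM", reaction_id, met)] += sign * (h / 2.0) * n
            return r
        if quantity in ("vmax_forward", "vmax_reverse"):
            base = "kcat_forward" if quantity == "vmax_forward" else "kcat_reverse"
            r = self.row(base, reaction_id=reaction_id)
            r[self.index("u", reaction_id=reaction_id)] += 1.0
            return r
        raise KeyError(f"unknown quantity {quantity!r}")

    def all_rows(self) -> list[tuple[str, Optional[str], Optional[str], np.ndarray]]:
        """Every basic and dependent quantity with its row, in fixed order."""
        out: list[tuple[str, Optional[str], Optional[str], np.ndarray]] = []
        for k in range(self.dim):
            q, rid, mid = self.basic_kind(k)
            row = np.zeros(self.dim)
            row[k] = 1.0
            out.append((q, rid, mid, row))
        for rid in self.reaction_ids:
            for q in ("keq", "kcat_forward", "kcat_reverse",
                      "vmax_forward", "vmax_reverse", "RA"):
                out.append((q, rid, None, self.row(q, reaction_id=rid)))
        for mid in self.metabolite_ids:
            out.append(("mu", None, mid, self.row("mu", metabolite_id=mid)))
        return out


def build_quantity_system(network: Network,
                          config: Optional[BalancingConfig] = None) -> QuantitySystem:
    return QuantitySystem(network, config)


@dataclass
class GaussianDistribution:
    """Prior or posterior over the basic quantity vector."""

    mean: np.ndarray
    cov: np.ndarray  # prior: diagonal; posterior: full SPD

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.ndim == 1:
            self.cov = np.diag(self.cov)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape does not match mean")

    @property
    def dim(self) -> int:
        return self.mean.size


def assemble_priors(system: QuantitySystem,
                    config: Optional[BalancingConfig] = None) -> GaussianDistribution:
    """Pseudo-prior over the basic vector (diagonal covariance)."""
    cfg = config or system.config
    mean = np.zeros(system.dim)
    var = np.zeros(system.dim)
    for k in range(system.dim):
        q, _, _ = system.basic_kind(k)
        median, std = cfg.pseudo_priors[q]
        mean[k] = median if q == "mu0" else math.log(median)
        var[k] = std * std
    return GaussianDistribution(mean, var)


def assemble_measurements(
    system: QuantitySystem,
    records: Sequence,
    default_log_std: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack measurement records into (design Q, values x, noise variances).

    Each record becomes one likelihood row: an identity row for a basic
    quantity, the dependency row for a dependent one. Values of
    multiplicative quantities are log-transformed.
    """
    sigma_default = default_log_std if default_log_std is not None \
        else system.config.default_log_std
    rows, values, variances, problems = [], [], [], []
    for rec in records:
        q = rec.quantity_type
        rid, mid = rec.reaction_id, rec.metabolite_id
        if rid is not None and rid not in system.network.reactions:
            problems.append(f"unknown reaction {rid!r} ({q})")
            continue
        if mid is not None and mid not in system.network.metabolites:
            problems.append(f"unknown metabolite {mid!r} ({q})")
            continue
        if q == "kM" and mid is None:
            problems.append(f"kM record for {rid!r} lacks a metabolite id")
            continue
        try:
            row = system.row(q, reaction_id=rid, metabolite_id=mid)
        except KeyError as exc:
            problems.append(str(exc))
            continue
        rows.append(row)
        values.append(math.log(rec.value) if q in MULTIPLICATIVE else rec.value)
        std = rec.uncertainty if getattr(rec, "uncertainty", None) else sigma_default
        variances.append(std * std)
    if problems:
        raise ValueError("invalid measurement records: " + "; ".join(problems))
    if not rows:
        return (np.zeros((0, system.dim)), np.zeros(0), np.zeros(0))
    return np.vstack(rows), np.array(values), np.array(variances)


def balance(
    prior: GaussianDistribution,
    measurements: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> GaussianDistribution:
    """Linear-Gaussian posterior over the basic vector.

    With no measurements the prior is returned unchanged (exactly). The
    precision-form update is solved via Cholesky with a 1e-10 jitter retry.
    """
    Q, x, noise_var = measurements
    if Q.shape[0] == 0:
        return GaussianDistribution(prior.mean.copy(), prior.cov.copy())
    # prior covariance is diagonal coming from assemble_priors; fall back to
    # a symmetric solve for a full prior covariance
    d = np.diag(prior.cov)
    if np.allclose(prior.cov, np.diag(d)):
        prior_prec = np.diag(1.0 / d)
    else:
        cf0 = scipy.linalg.cho_factor(prior.cov)
        prior_prec = scipy.linalg.cho_solve(cf0, np.eye(prior.dim))
    W = 1.0 / noise_var
    P = prior_prec + (Q.T * W) @ Q
    b = prior_prec @ prior.mean + Q.T @ (W * x)
    try:
        cf = scipy.linalg.cho_factor(P)
    except np.linalg.LinAlgError:
        try:
            cf = scipy.linalg.cho_factor(P + 1e-10 * np.eye(P.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular balancing system; tighten the pseudo-priors"
            ) from exc
    mean = scipy.linalg.cho_solve(cf, b)
    cov = scipy.linalg.cho_solve(cf, np.eye(P.shape[0]))
    cov = 0.5 * (cov + cov.T)
    return GaussianDistribution(mean, cov)


@dataclass
class BalancedParameters:
    """Median / mean / log-std for every basic and dependent quantity.

    Keys are (quantity, reaction_id, metabolite_id); medians of
    multiplicative quantities are exp of the posterior mean of their log.
    ``basic_mean``/``basic_cov`` retain the posterior over the basic vector
    so thermodynamically consistent draws can be taken later.
    """

    system: QuantitySystem
    means: dict[tuple[str, Optional[str], Optional[str]], float]
    stds: dict[tuple[str, Optional[str], Optional[str]], float]
    basic_mean: np.ndarray
    basic_cov: Optional[np.ndarray] = None

    def median(self, quantity: str, reaction_id: Optional[str] = None,
               metabolite_id: Optional[str] = None) -> float:
        m = self.means[(quantity, reaction_id, metabolite_id)]
        return math.exp(m) if quantity in MULTIPLICATIVE else m

    def log_mean(self, quantity: str, reaction_id: Optional[str] = None,
                 metabolite_id: Optional[str] = None) -> float:
        return self.means[(quantity, reaction_id, metabolite_id)]

    def concentrations(self) -> dict[str, float]:
        """Balanced metabolite concentrations (mM), the simulation initial state."""
        return {mid: self.median("c", metabolite_id=mid)
                for mid in self.system.metabolite_ids}

    def table(self) -> pd.DataFrame:
        recs = []
        for (q, rid, mid), mean in self.means.items():
            recs.append({
                "QuantityType": q,
                "ReactionID": rid or "",
                "CompoundID": mid or "",
                "Median": math.exp(mean) if q in MULTIPLICATIVE else mean,
                "Mean": mean,
                "LogStd": self.stds[(q, rid, mid)],
            })
        return pd.DataFrame(recs)


def derive_all_quantities(system: QuantitySystem,
                          posterior: GaussianDistribution) -> BalancedParameters:
    """Propagate the posterior to every basic and dependent quantity."""
    means: dict = {}
    stds: dict = {}
    for q, rid, mid, row in system.all_rows():
        means[(q, rid, mid)] = float(row @ posterior.mean)
        stds[(q, rid, mid)] = float(math.sqrt(max(row @ posterior.cov @ row, 0.0)))
    return BalancedParameters(system, means, stds,
                              posterior.mean.copy(), posterior.cov.copy())


def haldane_residuals(balanced: BalancedParameters, network: Network) -> np.ndarray:
    """h·ln keq − ln kcat+ + ln kcat− − h·Σ n ln kM, per reaction (should be ~0)."""
    out = np.zeros(len(network.reactions))
    for j, (rid, rxn) in enumerate(network.reactions.items()):
        res = rxn.cooperativity * balanced.log_mean("keq", reaction_id=rid)
        res -= balanced.log_mean("kcat_forward", reaction_id=rid)
        res += balanced.log_mean("kcat_reverse", reaction_id=rid)
        for met, n in rxn.stoichiometry.items():
            res -= rxn.cooperativity * n * balanced.log_mean(
                "kM", reaction_id=rid, metabolite_id=met)
        out[j] = res
    return out


def wegscheider_residuals(
    balanced: BalancedParameters, network: Network
) -> tuple[np.ndarray, np.ndarray]:
    """Cycle residuals Σ_j γ_j ln keq_j over a right-null-space basis of S.

    S is restricted to internal (non-boundary) metabolites. Returns
    (residuals, basis) where basis columns are the γ vectors; an acyclic
    network yields an empty residual set.
    """
    internal = network.internal_metabolite_ids()
    S = stoichiometric_matrix(network, internal)
    if S.size == 0:
        return np.zeros(0), np.zeros((len(network.reactions), 0))
    basis = scipy.linalg.null_space(S)
    ln_keq = np.array([balanced.log_mean("keq", reaction_id=rid)
                       for rid in network.reaction_ids])
    return basis.T @ ln_keq, basis


def sample_parameters(
    system: QuantitySystem,
    posterior: GaussianDistribution,
    width: float = 1.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> BalancedParameters:
    """Draw one full parameter set from the posterior.

    The *basic* vector is drawn from N(mean, width²·cov) and every dependent
    quantity is derived through its linear row, so each draw satisfies the
    Haldane and Wegscheider identities exactly. ``width = 0`` reproduces the
    medians.
    """
    if width < 0:
        raise ValueError("width must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if width == 0:
        q = posterior.mean.copy()
    else:
        try:
            L = np.linalg.cholesky(
                posterior.cov + 1e-12 * np.eye(posterior.dim))
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(
                posterior.cov + 1e-8 * np.eye(posterior.dim))
        q = posterior.mean + width * (L @ rng.standard_normal(posterior.dim))
    means: dict = {}
    stds: dict = {}
    for qt, rid, mid, row in system.all_rows():
        means[(qt, rid, mid)] = float(row @ q)
        stds[(qt, rid, mid)] = 0.0
    return BalancedParameters(system, means, stds, q, None)


def write_balanced_table(balanced: BalancedParameters, path: str) -> None:
    balanced.table().to_csv(path, sep="\t", index=False)
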
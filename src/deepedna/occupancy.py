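"""Multi-species, multi-scale Bayesian occupancy model.

The model separates true presence from imperfect detection across three
nested levels, matching the water-sampling design (sites are station x
sampling-depth combinations, each with triplicate water samples, each
sample amplified with several primer sets):

    z_ik  ~ Bernoulli(psi_ik),   logit(psi_ik) = beta0_k + beta1_k * depth_i
    a_ijk | z_ik ~ Bernoulli(z_ik * theta_k)
    y_ijmk | a_ijk ~ Bernoulli(a_ijk * p_mk),  logit(p_mk) = alpha_mk

z is site occupancy of taxon k (depth enters standardized), a is
availability of the taxon's DNA in water sample j, and p_mk is the
detection probability of marker m for taxon k.  Taxon-level parameters are
drawn from community normal hyperpriors (per marker for alpha), which lets
rarely detected taxa borrow strength and yields the community mean
detection probability per primer set, inv-logit(mu_alpha_m).

Inference is by MCMC with latent-state augmentation: z and a have
closed-form Bernoulli full conditionals; logit-scale coefficients use
adaptive random-walk Metropolis steps; community means are conjugate
normal updates and community scales use a random-walk on the log scale.
Convergence is reported via rank-normalized split R-hat and effective
sample size (flagged when R-hat >= 1.1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import ESVTable, SampleMeta
from .taxonomy import Assignment

logger = logging.getLogger("deepedna")


@dataclass
class DetectionArray:
    """Binary detections y[k, i, j, m] (taxon, site, water sample, marker).

    Missing cells are NaN; the missing pattern is identical across taxa
    (a water sample either was or was not amplified with a marker).
    """

    y: np.ndarray
    depth_m: np.ndarray
    taxa: list[str]
    sites: list[str]
    markers: list[str]

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 4:
            raise ValueError("y must be 4-dimensional (taxon, site, sample, marker)")
        finite = y[~np.isnan(y)]
        if not np.all((finite == 0) | (finite == 1)):
            raise ValueError("y entries must be 0, 1 or missing (NaN)")
        miss = np.isnan(y)
        if y.shape[0] > 1 and not (miss == miss[0]).all():
            raise ValueError("missing pattern must be identical across taxa")
        if len(self.depth_m) != y.shape[1]:
            raise ValueError("depth_m length must match the number of sites")
        self.y = y
        self.depth_m = np.asarray(self.depth_m, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.y.shape

    @property
    def depth_std(self) -> np.ndarray:
        d = self.depth_m
        sd = d.std()
        return (d - d.mean()) / sd if sd > 0 else np.zeros_like(d)


def build_detection_array(
    assignments: Sequence[Assignment],
    tables: Sequence[ESVTable],
    metadata: Sequence[SampleMeta],
    rank: str,
) -> DetectionArray:
    """Collapse read counts to binary taxon detections per site, water
    sample and marker.

    ``rank`` is ``"species"`` (taxa are species-level assignments) or
    ``"family"`` (all assignments with a named family, aggregated by
    family).  Sites are station x depth combinations of the non-control
    samples; the water samples within a site form the replicate axis.  A
    sample absent from a marker's ESV table was not amplified with that
    marker and yields missing cells.
    """
    if rank not in ("species", "family"):
        raise ValueError(f"rank must be 'species' or 'family', got {rank!r}")

    samples = [m for m in metadata if not m.is_control]
    site_of: dict[str, tuple] = {}
    for m in samples:
        site_of[m.sample_id] = (m.station, m.depth_m)
    sites = sorted(set(site_of.values()), key=str)
    site_idx = {s: i for i, s in enumerate(sites)}
    reps: dict[tuple, list[str]] = {s: [] for s in sites}
    for m in sorted(samples, key=lambda m: m.sample_id):
        reps[site_of[m.sample_id]].append(m.sample_id)
    J = max(len(v) for v in reps.values())
    rep_idx = {
        sid: (site_idx[site], j)
        for site, sids in reps.items()
        for j, sid in enumerate(sids)
    }

    taxon_of_esv: dict[tuple[str, str], str] = {}
    for a in assignments:
        name = a.assigned.species if rank == "species" else a.assigned.family
        if name:
            taxon_of_esv[(a.marker or "", a.esv_id)] = name
    taxa = sorted(set(taxon_of_esv.values()))
    taxon_idx = {t: k for k, t in enumerate(taxa)}
    markers = [t.marker for t in tables]

    K, I, M = len(taxa), len(sites), len(markers)
    y = np.full((K, I, J, M), np.nan)
    for m_i, table in enumerate(tables):
        observed = set(table.sample_ids)
        for sid, (i, j) in rep_idx.items():
            if sid in observed:
                y[:, i, j, m_i] = 0.0
        df = table.counts
        hit = df[df["read_count"] > 0]
        for esv_id, sid in zip(hit["esv_id"], hit["sample_id"]):
            taxon = taxon_of_esv.get((table.marker, str(esv_id)))
            if taxon is None or str(sid) not in rep_idx:
                continue
            i, j = rep_idx[str(sid)]
            y[taxon_idx[taxon], i, j, m_i] = 1.0
    n_miss = int(np.isnan(y[0]).sum())
    if n_miss:
        logger.info("detection array has %d missing (site, sample, marker) cells", n_miss)
    return DetectionArray(
        y=y,
        depth_m=np.array([s[1] for s in sites], dtype=float),
        taxa=taxa,
        sites=[f"{s[0]}@{s[1]:g}m" for s in sites],
        markers=markers,
    )


@dataclass(frozen=True)
class OccupancyPriors:
    """Weakly informative community hyperpriors (logit scales)."""

    mu_sd: float = 2.0  # Normal(0, mu_sd^2) on community means
    sigma_scale: float = 1.0  # Half-Normal(sigma_scale) on community SDs


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class OccupancyModel:
    """Hierarchical occupancy model for a :class:`DetectionArray`.

    ``fit`` runs the latent-state MCMC and returns an
    :class:`OccupancyResults`.  ``fix_theta`` / ``fix_detection`` clamp the
    availability and detection probabilities (the perfect-detection limit
    uses both at 1.0), removing their updates from the sampler.
    """

    def __init__(
        self,
        data: DetectionArray,
        priors: OccupancyPriors = OccupancyPriors(),
        fix_theta: Optional[float] = None,
        fix_detection: Optional[float] = None,
    ) -> None:
        self.data = data
        self.priors = priors
        self.fix_theta = fix_theta
        self.fix_detection = fix_detection

    # -- one MCMC chain ---------------------------------------------------

    def _run_chain(self, draws: int, burnin: int, rng: np.random.Generator):
        y = self.data.y  # (K, I, J, M)
        K, I, J, M = y.shape
        d = self.data.depth_std  # (I,)
        obs = ~np.isnan(y[0])  # (I, J, M) same across taxa
        obsf = obs.astype(float)
        y0 = np.nan_to_num(y, nan=0.0)
        forced = (y0 > 0).any(axis=3).transpose(1, 2, 0)  # (I, J, K): any marker saw it
        prior = self.priors
        eps = 1e-12

        # initial state
        beta0 = rng.normal(0, 0.5, K)
        beta1 = rng.normal(0, 0.5, K)
        lth = rng.normal(0, 0.5, K)
        alpha = rng.normal(0, 0.5, (M, K))
        mu_b0 = mu_b1 = mu_th = 0.0
        sg_b0 = sg_b1 = sg_th = 1.0
        mu_a = np.zeros(M)
        sg_a = np.ones(M)
        z = np.ones((I, K))
        a = forced.astype(float).copy()

        # adaptive RW scales
        s_b0 = np.full(K, 0.5)
        s_b1 = np.full(K, 0.5)
        s_th = np.full(K, 0.5)
        s_al = np.full((M, K), 0.5)
        s_sh = np.full(K, 0.5)
        s_sg = 0.3

        def mh_logit_binomial(x, n1, ntr, mu, sg, scale):
            """Vector Metropolis step for logit-scale probabilities with
            Binomial(n1 of ntr) likelihood and Normal(mu, sg) prior."""
            prop = x + rng.normal(0, 1, x.shape) * scale
            def logpost(v):
                return n1 * v - ntr * _softplus(v) - 0.5 * ((v - mu) / sg) ** 2
            acc = np.log(rng.uniform(size=x.shape)) < logpost(prop) - logpost(x)
            return np.where(acc, prop, x), acc

        def mh_sigma(sg, values, mu, scale):
            prop = sg * np.exp(rng.normal(0, scale, np.shape(sg)))
            def logpost(s):
                return (
                    -np.size(values, -1) * np.log(s)
                    - 0.5 * np.sum((values - np.expand_dims(mu, -1)) ** 2, axis=-1) / s**2
                    - 0.5 * (s / prior.sigma_scale) ** 2
                    + np.log(s)  # Jacobian of the log-scale walk
                )
            acc = np.log(rng.uniform(size=np.shape(prop))) < logpost(prop) - logpost(sg)
            return np.where(acc, prop, sg)

        def conj_mu(values, sg):
            n = np.size(values, -1)
            prec = n / sg**2 + 1.0 / prior.mu_sd**2
            mean = np.sum(values, axis=-1) / sg**2 / prec
            return rng.normal(mean, 1.0 / np.sqrt(prec))

        kept: dict[str, list] = {k: [] for k in (
            "beta0", "beta1", "theta", "alpha", "mu_beta0", "sigma_beta0",
            "mu_beta1", "sigma_beta1", "mu_theta", "sigma_theta",
            "mu_alpha", "sigma_alpha",
        )}
        acc_counts = {"b0": np.zeros(K), "b1": np.zeros(K), "th": np.zeros(K),
                      "al": np.zeros((M, K)), "sh": np.zeros(K)}
        batch = 50

        for it in range(draws + burnin):
            if self.fix_detection is not None:
                p = np.full((M, K), np.clip(self.fix_detection, eps, 1 - eps))
            else:
                p = expit(alpha)
            if self.fix_theta is not None:
                theta = np.full(K, np.clip(self.fix_theta, eps, 1 - eps))
            else:
                theta = expit(lth)
            psi = expit(beta0[None, :] + beta1[None, :] * d[:, None])  # (I, K)

            # a | rest  (forced to 1 wherever a marker detected the taxon)
            log1mp = np.log1p(-np.clip(p, None, 1 - 1e-15))  # (M, K)
            q = np.exp(np.einsum("ijm,mk->ijk", obsf, log1mp))  # (I, J, K)
            pa = z[:, None, :] * theta[None, None, :]
            num = pa * q
            denom = num + (1.0 - pa)
            pr_a = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
            a = np.where(forced, 1.0, (rng.uniform(size=pr_a.shape) < pr_a).astype(float))

            # z | rest
            any_a = a.max(axis=1) > 0  # (I, K)
            no_det = (1.0 - theta[None, :]) ** J
            numz = psi * no_det
            pr_z = numz / (numz + (1.0 - psi))
            z = np.where(any_a, 1.0, (rng.uniform(size=pr_z.shape) < pr_z).astype(float))

            # alpha | rest  (Bernoulli trials at available samples)
            ntr = np.einsum("ijk,ijm->mk", a, obsf)
            n1 = np.einsum("kijm,ijm->mk", y0, obsf)  # y=1 implies a=1
            if self.fix_detection is None:
                alpha, acc = mh_logit_binomial(alpha, n1, ntr, mu_a[:, None], sg_a[:, None], s_al)
                acc_counts["al"] += acc

            # theta | rest (trials at occupied sites)
            ntr_t = J * z.sum(axis=0)  # (K,)
            n1_t = np.einsum("ijk,ik->k", a, z)
            if self.fix_theta is None:
                lth, acc = mh_logit_binomial(lth, n1_t, ntr_t, mu_th, sg_th, s_th)
                acc_counts["th"] += acc

            # joint shift per taxon: trade availability against detection
            # (these two are strongly anti-correlated in the posterior, so a
            # coordinated move mixes far better than the axis updates alone)
            if self.fix_detection is None and self.fix_theta is None:
                delta = rng.normal(0, 1, K) * s_sh

                def shift_logpost(lth_v, alpha_v):
                    lp = (
                        n1_t * lth_v
                        - ntr_t * _softplus(lth_v)
                        - 0.5 * ((lth_v - mu_th) / sg_th) ** 2
                    )
                    lp += np.sum(
                        n1 * alpha_v
                        - ntr * _softplus(alpha_v)
                        - 0.5 * ((alpha_v - mu_a[:, None]) / sg_a[:, None]) ** 2,
                        axis=0,
                    )
                    return lp

                lp_new = shift_logpost(lth + delta, alpha - delta[None, :])
                lp_old = shift_logpost(lth, alpha)
                acc = np.log(rng.uniform(size=K)) < lp_new - lp_old
                lth = np.where(acc, lth + delta, lth)
                alpha = np.where(acc[None, :], alpha - delta[None, :], alpha)
                acc_counts["sh"] += acc

            # beta0, beta1 | z
            zs = z.sum(axis=0)
            def z_loglik(b0, b1):
                eta = b0[None, :] + b1[None, :] * d[:, None]
                return np.sum(z * eta - _softplus(eta), axis=0)
            prop = beta0 + rng.normal(0, 1, K) * s_b0
            lp_new = z_loglik(prop, beta1) - 0.5 * ((prop - mu_b0) / sg_b0) ** 2
            lp_old = z_loglik(beta0, beta1) - 0.5 * ((beta0 - mu_b0) / sg_b0) ** 2
            acc = np.log(rng.uniform(size=K)) < lp_new - lp_old
            beta0 = np.where(acc, prop, beta0)
            acc_counts["b0"] += acc
            prop = beta1 + rng.normal(0, 1, K) * s_b1
            lp_new = z_loglik(beta0, prop) - 0.5 * ((prop - mu_b1) / sg_b1) ** 2
            lp_old = z_loglik(beta0, beta1) - 0.5 * ((beta1 - mu_b1) / sg_b1) ** 2
            acc = np.log(rng.uniform(size=K)) < lp_new - lp_old
            beta1 = np.where(acc, prop, beta1)
            acc_counts["b1"] += acc

            # community hyperparameters
            mu_b0 = conj_mu(beta0, sg_b0)
            sg_b0 = float(mh_sigma(sg_b0, beta0, mu_b0, s_sg))
            mu_b1 = conj_mu(beta1, sg_b1)
            sg_b1 = float(mh_sigma(sg_b1, beta1, mu_b1, s_sg))
            if self.fix_theta is None:
                mu_th = conj_mu(lth, sg_th)
                sg_th = float(mh_sigma(sg_th, lth, mu_th, s_sg))
            if self.fix_detection is None:
                mu_a = conj_mu(alpha, sg_a)
                sg_a = mh_sigma(sg_a, alpha, mu_a, s_sg)

            # scale adaptation toward ~0.44 acceptance (burn-in only)
            if it < burnin and (it + 1) % batch == 0:
                step = min(0.25, 2.0 / np.sqrt((it + 1) / batch))
                for key, scales in (("b0", s_b0), ("b1", s_b1), ("th", s_th),
                                    ("al", s_al), ("sh", s_sh)):
                    rate = acc_counts[key] / batch
                    scales *= np.exp(step * (rate - 0.44))
                    acc_counts[key][...] = 0.0

            if it >= burnin:
                kept["beta0"].append(beta0.copy())
                kept["beta1"].append(beta1.copy())
                kept["theta"].append(
                    theta.copy() if self.fix_theta is not None else expit(lth)
                )
                # alpha draws are kept on the logit scale
                kept["alpha"].append(
                    logit(p).copy() if self.fix_detection is not None else alpha.copy()
                )
                kept["mu_beta0"].append(mu_b0)
                kept["sigma_beta0"].append(sg_b0)
                kept["mu_beta1"].append(mu_b1)
                kept["sigma_beta1"].append(sg_b1)
                kept["mu_theta"].append(mu_th)
                kept["sigma_theta"].append(sg_th)
                kept["mu_alpha"].append(mu_a.copy())
                kept["sigma_alpha"].append(sg_a.copy())

        return {k: np.asarray(v) for k, v in kept.items()}

    def fit(
        self,
        draws: int = 2000,
        burnin: int = 1000,
        chains: int = 4,
        seed: int = 0,
        ) -> "OccupancyResults":
        """Sample the posterior; returns results with draws stacked as
        (chain, draw, ...)."""
        if chains < 1:
            raise ValueError("need at least 1 chain")
        if chains < 2:
            logger.warning("single chain: R-hat will be unavailable")
        seqs = np.random.SeedSequence(seed).spawn(chains)
        chain_draws = [self._run_chain(draws, burnin, np.random.default_rng(s)) for s in seqs]
        posterior = {
            k: np.stack([c[k] for c in chain_draws]) for k in chain_draws[0]
        }
        return OccupancyResults(self, posterior)


def _scalar_views(posterior: Mapping[str, np.ndarray], markers, taxa):
    """Yield (name, (chain, draw) array) pairs for every scalar parameter."""
    for key, arr in posterior.items():
        if arr.ndim == 2:
            yield key, arr
        elif arr.ndim == 3:
            labels = markers if arr.shape[2] == len(markers) and key.endswith("alpha") else taxa
            for j in range(arr.shape[2]):
                yield f"{key}[{labels[j]}]", arr[:, :, j]
        elif arr.ndim == 4:
            for m in range(arr.shape[2]):
                for k in range(arr.shape[3]):
                    yield f"{key}[{markers[m]},{taxa[k]}]", arr[:, :, m, k]


def summarize_posterior(
    draws: Mapping[str, np.ndarray] | np.ndarray,
    markers: Sequence[str] = (),
    taxa: Sequence[str] = (),
) -> pd.DataFrame:
    """Posterior summary table: mean, median, 95% interval, R-hat, ESS.

    ``draws`` maps parameter names to (chain, draw, ...) arrays (or is a
    single such array).  R-hat is the rank-normalized split statistic; with
    a single chain it is reported as NaN with a warning, and parameters
    with R-hat >= 1.1 are flagged as not converged.
    """
    if isinstance(draws, np.ndarray):
        draws = {"param": draws}
    rows = []
    for name, arr in _scalar_views(draws, list(markers), list(taxa)):
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[1] < 2:
            raise ValueError("each parameter needs >= 2 draws shaped (chain, draw)")
        flat = arr.ravel()
        if arr.shape[0] < 2:
            logger.warning("parameter %s: single chain, R-hat unavailable", name)
            rhat = np.nan
        elif np.ptp(arr) == 0:
            logger.warning("parameter %s: constant chains, R-hat undefined", name)
            rhat = np.nan
        else:
            rhat = float(az.rhat(arr))
        ess = float(az.ess(arr)) if np.ptp(arr) > 0 else np.nan
        rows.append(
            {
                "param": name,
                "mean": float(flat.mean()),
                "median": float(np.median(flat)),
                "q2.5": float(np.quantile(flat, 0.025)),
                "q97.5": float(np.quantile(flat, 0.975)),
                "rhat": rhat,
                "ess": ess,
                "converged": bool(rhat < 1.1) if np.isfinite(rhat) else False,
            }
        )
    return pd.DataFrame(rows)


class OccupancyResults:
    """Posterior draws and summaries of a fitted occupancy model."""

    def __init__(self, model: OccupancyModel, posterior: dict[str, np.ndarray]):
        self.model = model
        self.posterior = posterior
        self._summary: Optional[pd.DataFrame] = None

    @property
    def data(self) -> DetectionArray:
        return self.model.data

    def summary(self) -> pd.DataFrame:
        if self._summary is None:
            self._summary = summarize_posterior(
                self.posterior, self.data.markers, self.data.taxa
            )
            bad = self._summary[
                np.isfinite(self._summary["rhat"]) & (self._summary["rhat"] >= 1.1)
            ]
            if len(bad):
                logger.warning(
                    "%d parameter(s) with R-hat >= 1.1 (worst %.3f): chains may not "
                    "have converged", len(bad), bad["rhat"].max(),
                )
        return self._summary

    @property
    def converged(self) -> bool:
        s = self.summary()
        rh = s["rhat"][np.isfinite(s["rhat"])]
        return bool((rh < 1.1).all()) if len(rh) else False

    def community_mean_detection(self, marker: str) -> np.ndarray:
        """Posterior draws of inv-logit(mu_alpha) for one primer set."""
        if marker not in self.data.markers:
            raise ValueError(f"unknown marker {marker!r}; have {self.data.markers}")
        m = self.data.markers.index(marker)
        return expit(self.posterior["mu_alpha"][:, :, m]).ravel()

    def detection_prob(self, marker: str, taxon: str) -> np.ndarray:
        """Posterior draws of p_mk = inv-logit(alpha_mk)."""
        m = self.data.markers.index(marker)
        k = self.data.taxa.index(taxon)
        return expit(self.posterior["alpha"][:, :, m, k]).ravel()

    def occupancy_prob(self) -> np.ndarray:
        """Posterior draws of psi_ik, shaped (draw, site, taxon)."""
        b0 = self.posterior["beta0"].reshape(-1, len(self.data.taxa))
        b1 = self.posterior["beta1"].reshape(-1, len(self.data.taxa))
        d = self.data.depth_std
        return expit(b0[:, None, :] + b1[:, None, :] * d[None, :, None])

    def plot_detection_probabilities(self, ax=None):
        """Boxplots of per-taxon detection probability by primer set."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.5 + 0.5 * len(self.data.taxa), 4))
        K = len(self.data.taxa)
        M = len(self.data.markers)
        width = 0.8 / M
        for m, marker in enumerate(self.data.markers):
            data = [expit(self.posterior["alpha"][:, :, m, k]).ravel() for k in range(K)]
            pos = np.arange(K) + (m - (M - 1) / 2) * width
            ax.boxplot(data, positions=pos, widths=width * 0.9, showfliers=False)
        ax.set_xticks(np.arange(K))
        ax.set_xticklabels(self.data.taxa, rotation=90)
        ax.set_ylabel("detection probability")
        return ax

    def plot_community_detection(self, ax=None):
        """Boxplot of community mean detection per primer set."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        data = [self.community_mean_detection(m) for m in self.data.markers]
        ax.boxplot(data, tick_labels=self.data.markers, showfliers=False)
        ax.set_ylabel("community mean detection probability")
        return ax


def fit_occupancy(
    data: DetectionArray,
    draws: int = 2000,
    burnin: int = 1000,
    chains: int = 4,
    seed: int = 0,
    priors: OccupancyPriors = OccupancyPriors(),
    fix_theta: Optional[float] = None,
    fix_detection: Optional[float] = None,
) -> OccupancyResults:
    """Convenience wrapper: build the model and sample its posterior."""
    model = OccupancyModel(data, priors, fix_theta=fix_theta, fix_detection=fix_detection)
    return model.fit(draws=draws, burnin=burnin, chains=chains, seed=seed)
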
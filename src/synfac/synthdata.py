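"""Synthetic two-group cohort generator with planted factor structure.

The generator emulates the statistical skeleton of a multi-site
case-control resting-state fMRI study: every subject is a stable VAR(1)
process over N parcellated regions, and patients differ from controls by
an attenuation of cross-regional couplings concentrated on K planted
factor patterns, mixed per subject with Dirichlet loadings.  Attenuating
couplings (rather than inflating noise) removes cross-predictive
structure, which is exactly what the persistent-synergy atom measures, so
patients show reduced pairwise synergy on planted pairs.  Clinical scores
are linear in the loadings plus noise; gene expression and structural
maps are smooth fields on the synthetic coordinates with planted
factor-correlated genes.

Everything is a pure function of (arguments, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import InvalidArgumentError
from .infodynamics import RegionalTimeSeries
from .util import lower_pairs, n_pairs

CORTICAL_NETWORKS = ("VIS", "SOM", "DAN", "SAL", "LIM", "FPN", "DMN")
ALL_NETWORKS = CORTICAL_NETWORKS + ("SUB",)

#: PANSS subscale ranges: positive, negative, general psychopathology.
PANSS_RANGES = {"pos": (7, 49), "neg": (7, 49), "gen": (16, 112)}
PANSS_N_ITEMS = {"pos": 7, "neg": 7, "gen": 16}


@dataclass
class Parcellation:
    """Region lookup table: labels, network assignment, 3-D coordinates."""

    region_id: np.ndarray
    label: list
    network: list
    hemisphere: list
    coord: np.ndarray  # (N, 3), arbitrary mm units
    is_cortical: np.ndarray

    @property
    def n_regions(self) -> int:
        return len(self.region_id)

    def distance_matrix(self) -> np.ndarray:
        return cdist(self.coord, self.coord)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_id,
                "label": self.label,
                "network": self.network,
                "hemisphere": self.hemisphere,
                "x": self.coord[:, 0],
                "y": self.coord[:, 1],
                "z": self.coord[:, 2],
                "is_cortical": self.is_cortical.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        return cls(
            region_id=df["region_id"].to_numpy(),
            label=list(df["label"]),
            network=list(df["network"]),
            hemisphere=list(df["hemisphere"]),
            coord=df[["x", "y", "z"]].to_numpy(float),
            is_cortical=df["is_cortical"].to_numpy().astype(bool),
        )


@dataclass
class PlantedTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    factor_patterns: np.ndarray  # (K, P) nonnegative, rows sum to 1
    loadings: np.ndarray  # (S_scz, K) rows on the simplex
    clinical_weights: np.ndarray  # (K, 3) loading -> PANSS subscale map
    risk_gene_index: dict = field(default_factory=dict)  # factor -> gene ids
    factor_blocks: list = field(default_factory=list)  # region index blocks
    attenuation_weights: np.ndarray | None = None  # (K, P) mechanism weights

    def factor_maps(self, n_regions: int) -> np.ndarray:
        """Planted regional maps: per region, summed pattern mass of its pairs."""
        i, j = lower_pairs(n_regions)
        maps = np.zeros((self.factor_patterns.shape[0], n_regions))
        for k, pat in enumerate(self.factor_patterns):
            np.add.at(maps[k], i, pat)
            np.add.at(maps[k], j, pat)
        return maps


def _sphere_points(rng, n, center, radius):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return center + radius * v


def make_parcellation(
    n_cortical: int = 100, n_subcortical: int = 15, seed: int = 0
) -> Parcellation:
    """Synthetic whole-brain parcellation on two hemispheric spheres.

    Cortical regions are split into the seven canonical resting-state
    networks in contiguous, near-equal blocks; subcortical regions all
    carry the SUB label.  Coordinates are sampled on a sphere per
    hemisphere (cortex) and near the midline (subcortex).
    """
    if n_cortical < 8:
        raise InvalidArgumentError("n_cortical must be >= 8")
    if n_subcortical < 0:
        raise InvalidArgumentError("n_subcortical must be >= 0")
    rng = np.random.default_rng(seed)
    n = n_cortical + n_subcortical
    sizes = np.full(7, n_cortical // 7)
    sizes[: n_cortical % 7] += 1
    networks, labels, hemis = [], [], []
    ridx = 0
    for net, sz in zip(CORTICAL_NETWORKS, sizes):
        for k in range(sz):
            hemi = "L" if ridx % 2 == 0 else "R"
            networks.append(net)
            hemis.append(hemi)
            labels.append(f"{hemi}_{net}_{k}")
            ridx += 1
    for k in range(n_subcortical):
        hemi = "L" if k % 2 == 0 else "R"
        networks.append("SUB")
        hemis.append(hemi)
        labels.append(f"{hemi}_SUB_{k}")
    coords = np.zeros((n, 3))
    for idx in range(n):
        if idx < n_cortical:
            center = np.array([-32.0, 0.0, 10.0]) if hemis[idx] == "L" else np.array([32.0, 0.0, 10.0])
            coords[idx] = _sphere_points(rng, 1, center, 45.0)
        else:
            center = np.array([-10.0, -5.0, -5.0]) if hemis[idx] == "L" else np.array([10.0, -5.0, -5.0])
            coords[idx] = _sphere_points(rng, 1, center, 12.0)
    is_cortical = np.arange(n) < n_cortical
    return Parcellation(
        region_id=np.arange(n),
        label=labels,
        network=networks,
        hemisphere=hemis,
        coord=coords,
        is_cortical=is_cortical,
    )


# ---------------------------------------------------------------------------
# Cohort simulation

#: nominal standard deviation of the pairwise synergy estimator at T samples,
#: calibrated once against the VAR(1) law used by this generator
_SYN_EST_SD_SCALE = 1.4


def _planted_structure(n_regions: int, K: int) -> tuple[np.ndarray, list]:
    """Attenuation weights: K disjoint within-block pair indicators.

    Each factor owns a contiguous block of regions; its attenuation
    pattern is 1 on pairs with both endpoints in the block, 0 elsewhere.
    """
    blocks = np.array_split(np.arange(n_regions), K)
    i, j = lower_pairs(n_regions)
    att_w = np.zeros((K, n_pairs(n_regions)))
    for k, blk in enumerate(blocks):
        members = np.isin(i, blk) & np.isin(j, blk)
        att_w[k, members] = 1.0
    return att_w, [b.tolist() for b in blocks]


def _base_coupling(rng, n_regions, blocks):
    """Stable VAR(1) coupling: one signed cycle per factor block.

    Every region has weak self-memory and two strong couplings to its
    cycle neighbours within its own factor block, plus sparse weak
    background couplings; this keeps pair dynamics homogeneous so the
    response to coupling attenuation is uniform over a block.
    """
    A = np.zeros((n_regions, n_regions))
    np.fill_diagonal(A, 0.25)
    for blk in blocks:
        L = len(blk)
        for t in range(L):
            a, b = blk[t], blk[(t + 1) % L]
            s = rng.choice([-1.0, 1.0])
            A[a, b] = A[b, a] = 0.35 * s
    mask = rng.random((n_regions, n_regions)) < 0.04
    np.fill_diagonal(mask, False)
    A[mask] += rng.normal(0.0, 0.04, size=int(mask.sum()))
    off = ~np.eye(n_regions, dtype=bool)
    rho = np.max(np.abs(np.linalg.eigvals(A)))
    scale = 1.0
    while rho > 0.95:
        scale *= 0.97
        B = A.copy()
        B[off] = A[off] * scale
        rho = np.max(np.abs(np.linalg.eigvals(B)))
    A[off] *= scale
    return A


def _expected_dysfunction_patterns(A, att_w, effect, T, i, j):
    """Expected document-space dysfunction pattern of a pure-factor patient.

    The population synergy of every pair is computed analytically from
    the VAR(1) law before and after a pure (loading = 1) attenuation of
    factor k; the drop, expressed in units of the nominal estimator noise
    sd at T samples, is passed through the expectation of the document
    rule w = max(0, -z), and the uniform noise floor is subtracted.
    """
    from scipy.stats import norm

    from .infodynamics import analytic_pair_synergy

    syn0 = analytic_pair_synergy(A)
    sd_nom = _SYN_EST_SD_SCALE / np.sqrt(T)
    K = att_w.shape[0]
    patterns = np.zeros_like(att_w)
    for k in range(K):
        atten = 1.0 - effect * att_w[k]
        Ak = A.copy()
        Ak[i, j] *= atten
        Ak[j, i] *= atten
        mu = (analytic_pair_synergy(Ak) - syn0) / sd_nom  # expected z shift
        w = norm.pdf(mu) - mu * norm.cdf(-mu) - norm.pdf(0.0)
        w = np.maximum(w, 0.0)
        total = w.sum()
        patterns[k] = w / total if total > 0 else w
    return patterns


def _stabilize(A: np.ndarray) -> np.ndarray:
    """Shrink off-diagonal couplings until the spectral radius is < 0.97."""
    off = ~np.eye(A.shape[0], dtype=bool)
    out = A.copy()
    while np.max(np.abs(np.linalg.eigvals(out))) >= 0.97:
        out[off] *= 0.95
    return out


def _simulate_var(rng, A, T, noise_scale=1.0, burn_in=100):
    n = A.shape[0]
    x = np.zeros(n)
    eps = rng.normal(scale=noise_scale, size=(burn_in + T, n))
    out = np.empty((T, n))
    for t in range(burn_in + T):
        x = A @ x + eps[t]
        if t >= burn_in:
            out[t - burn_in] = x
    return out


def simulate_cohort(
    parcellation: Parcellation,
    n_nc: int = 60,
    n_scz: int = 60,
    T: int = 240,
    K: int = 3,
    effect: float = 0.6,
    seed: int = 0,
    n_sites: int = 3,
    loading_concentration: float = 0.35,
    clinical_noise_sd: float = 3.2,
) -> tuple[pd.DataFrame, list[RegionalTimeSeries], PlantedTruth]:
    """Simulate a two-group cohort of VAR(1) regional time series.

    Controls share a stable coupling matrix A; for each patient the
    off-diagonal couplings of pair (i, j) are multiplied by
    ``1 - effect * sum_k loading_k * attenuation_k(i, j)`` where
    attenuation_k is the within-block indicator of factor k, so
    high-loading subjects lose the cross-predictive structure inside
    their factor's region block.  The planted dysfunction patterns stored
    in the returned truth are the analytically expected document-space
    reduction profiles of pure-factor patients (which extend beyond the
    attenuated pairs, because losing drive lowers a region's temporal
    predictability and hence the synergy of every pair it belongs to).
    PANSS subscales are linear in the loadings plus Gaussian noise,
    affinely mapped into the instruments' ranges; demographics and site
    are independent of the loadings.  Sites differ only by a small
    additive measurement-noise level.
    """
    if T < 50:
        raise InvalidArgumentError("T must be >= 50")
    if not 0.0 <= effect <= 1.0:
        raise InvalidArgumentError("effect must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    N = parcellation.n_regions
    i, j = lower_pairs(N)
    att_w, blocks = _planted_structure(N, K)
    A = _base_coupling(rng, N, blocks)
    loadings = rng.dirichlet(np.full(K, loading_concentration), size=n_scz)
    patterns = _expected_dysfunction_patterns(A, att_w, effect, T, i, j)

    site_obs_noise = 0.15 * np.arange(n_sites)

    series: list[RegionalTimeSeries] = []
    rows = []
    sub_idx = 0
    for group, count in (("NC", n_nc), ("SCZ", n_scz)):
        for g_idx in range(count):
            site = g_idx % n_sites
            if group == "NC":
                A_s = A
            else:
                load = loadings[g_idx]
                atten = 1.0 - effect * (load @ att_w)
                A_s = A.copy()
                A_s[i, j] *= atten
                A_s[j, i] *= atten
                A_s = _stabilize(A_s)
            data = _simulate_var(rng, A_s, T)
            if site_obs_noise[site] > 0:
                data = data + rng.normal(0.0, site_obs_noise[site], data.shape)
            sid = f"sub-{sub_idx:04d}"
            series.append(RegionalTimeSeries(subject_id=sid, data=data))
            rows.append({"subject_id": sid, "group": group, "site": f"site{site}"})
            sub_idx += 1

    cohort = pd.DataFrame(rows)
    S = len(cohort)
    cohort["age"] = np.clip(rng.normal(30, 8, S), 18, 60).round(1)
    cohort["gender"] = rng.choice(["M", "F"], size=S)
    cohort["motion"] = np.abs(rng.normal(0.10, 0.04, S)).round(4)
    cohort["gmv"] = rng.normal(600, 50, S).round(1)

    # clinical scores: subscale = weights . loadings + noise, mapped to range
    clinical_weights = np.array(
        [[1.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, -1.0, -1.0]], dtype=float
    )[:K, :]
    raw = loadings @ clinical_weights + rng.normal(
        0.0, clinical_noise_sd * loadings.std(axis=0).mean(), size=(n_scz, 3)
    )
    zraw = (raw - raw.mean(axis=0)) / raw.std(axis=0)
    scz_mask = cohort["group"] == "SCZ"
    for col, key, z in zip(
        ("PANSS_pos", "PANSS_neg", "PANSS_gen"), ("pos", "neg", "gen"), zraw.T
    ):
        lo, hi = PANSS_RANGES[key]
        mid, span = (lo + hi) / 2, (hi - lo) / 2
        vals = np.clip(mid + 0.45 * span * z, lo, hi)
        cohort.loc[scz_mask, col] = vals.round(1)

    # item scores: subscale split evenly across items plus noise, clipped 1..7
    item_cols = {}
    for key in ("pos", "neg", "gen"):
        sub_col = f"PANSS_{key}"
        for it in range(PANSS_N_ITEMS[key]):
            base = cohort.loc[scz_mask, sub_col].to_numpy() / PANSS_N_ITEMS[key]
            item_cols[f"panss_{key}{it + 1}"] = np.clip(
                base + rng.normal(0, 0.5, n_scz), 1, 7
            ).round(1)
    for col, vals in item_cols.items():
        cohort.loc[scz_mask, col] = vals

    cohort.loc[scz_mask, "cpz_eq"] = rng.lognormal(5.9, 0.5, n_scz).round(0)
    cohort.loc[scz_mask, "illness_duration"] = np.abs(
        rng.normal(8, 5, n_scz)
    ).round(1)

    truth = PlantedTruth(
        factor_patterns=patterns,
        loadings=loadings,
        clinical_weights=clinical_weights,
        factor_blocks=blocks,
        attenuation_weights=att_w,
    )
    return cohort, series, truth


# ---------------------------------------------------------------------------
# Gene expression and structural maps


def _smooth_field(rng, distmat, length_scale, n_fields=1):
    """Spatially smooth Gaussian fields via an exponential-decay kernel."""
    kern = np.exp(-distmat / length_scale)
    raw = kern @ rng.normal(size=(distmat.shape[0], n_fields))
    raw -= raw.mean(axis=0)
    raw /= raw.std(axis=0)
    return raw


def simulate_gene_expression(
    parcellation: Parcellation,
    n_genes: int = 1000,
    factor_maps: np.ndarray | None = None,
    n_planted: int = 50,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Region x gene expression with genes planted on the factor maps.

    Planted genes equal a (z-scored) factor map plus Gaussian noise; half
    of them get the negated map so that both tails of the gene-factor
    correlation ranking are populated.  The remaining genes are smooth
    spatial noise.  Returns the expression table and the planted gene ids
    per factor.
    """
    if n_genes <= 0:
        raise InvalidArgumentError("n_genes must be positive")
    K = 0 if factor_maps is None else factor_maps.shape[0]
    if n_planted * K > n_genes:
        raise InvalidArgumentError("n_planted * K exceeds n_genes")
    rng = np.random.default_rng(seed)
    N = parcellation.n_regions
    dist = parcellation.distance_matrix()
    expr = _smooth_field(rng, dist, length_scale=25.0, n_fields=n_genes)
    gene_ids = [f"g{k:05d}" for k in range(n_genes)]
    planted: dict[int, list[str]] = {}
    g = 0
    for k in range(K):
        fmap = factor_maps[k]
        zmap = (fmap - fmap.mean()) / fmap.std()
        ids = []
        for p in range(n_planted):
            sign = 1.0 if p < (n_planted + 1) // 2 else -1.0
            expr[:, g] = sign * zmap + rng.normal(0, noise_sd, N)
            ids.append(gene_ids[g])
            g += 1
        planted[k] = ids
    expr -= expr.mean(axis=0)
    sd = expr.std(axis=0)
    sd[sd == 0] = 1.0
    expr /= sd
    table = pd.DataFrame(expr, columns=gene_ids)
    table.insert(0, "region_id", parcellation.region_id)
    table = table.set_index("region_id")
    return table, planted


def simulate_structural(
    parcellation: Parcellation, density: float = 0.3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distance-decaying structural connectome plus myelin/gradient maps.

    The connectome is symmetric, nonnegative, zero-diagonal, thresholded
    to the requested edge density and rescaled to unit maximum.  Myelin
    and gradient maps are smooth z-scored fields on the coordinates.
    """
    if not 0.0 < density <= 1.0:
        raise InvalidArgumentError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    dist = parcellation.distance_matrix()
    n = parcellation.n_regions
    lam = np.median(dist[dist > 0])
    w = np.exp(-dist / (0.35 * lam)) * rng.lognormal(0.0, 0.4, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    if density < 1.0:
        i, j = lower_pairs(n)
        vals = w[i, j]
        kth = np.quantile(vals, 1.0 - density)
        keep = vals >= kth
        sc = np.zeros_like(w)
        sc[i[keep], j[keep]] = vals[keep]
        sc = sc + sc.T
    else:
        sc = w
    sc /= sc.max()
    maps = _smooth_field(rng, dist, length_scale=30.0, n_fields=2)
    myelin, gradient = maps[:, 0], maps[:, 1]
    return sc, myelin, gradient
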
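"""Structure-based mode-of-action grouping and two-stage prediction (TSP).

Components are grouped into putative mode-of-action (MoA) clusters from
2-D molecular descriptors (standardized, PCA-compressed, k-means
clustered); concentration addition is applied within each cluster and
independent action across clusters.  Binary mixtures bypass clustering:
an ECFP6 (Morgan radius-3, 2048-bit) Tanimoto similarity above 0.7 selects
CA, otherwise IA.

The descriptor block is RDKit's standard 2-D set (~210 descriptors).
Commercial descriptor engines compute far larger blocks, so cluster
assignments — and hence TSP predictions — are a documented approximation
of any tool built on such engines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem import rdFingerprintGenerator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .drc import EffectUnattainableError
from .mixture import MixtureSpec, gca_effect

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoAClustering",
    "StructureError",
    "parse_structure",
    "compute_descriptor_matrix",
    "pca_reduce",
    "cluster_moa",
    "select_k",
    "ecfp6_tanimoto",
    "binary_moa_rule",
    "cluster_mixture",
    "tsp_effect",
    "tsp_effective_concentration",
]

DEFAULT_CLUSTER_SEED = 20220525
SIMILARITY_THRESHOLD = 0.7

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048)


class StructureError(ValueError):
    """Unparseable molecular structure."""


@dataclass(frozen=True)
class MoAClustering:
    """Result of the MoA grouping stage.

    For >= 3 components: descriptor/PCA provenance, chosen k and labels.
    For binary mixtures the ECFP6 Tanimoto similarity and the CA/IA choice
    are recorded instead (labels encode the choice: identical labels for
    CA, distinct for IA).
    """

    n_components_in: int
    labels: tuple[int, ...]
    descriptor_dim: int = 0
    n_pcs: int = 0
    k: int = 0
    seed: int = DEFAULT_CLUSTER_SEED
    silhouette: float | None = None
    explained_variance: float | None = None
    binary_similarity: float | None = None
    binary_choice: str | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != self.n_components_in:
            raise ValueError("one cluster label per component required")
        binary = self.n_components_in == 2
        if binary != (self.binary_similarity is not None):
            raise ValueError("binary similarity present iff the mixture is binary")
        if self.binary_similarity is not None and not 0 <= self.binary_similarity <= 1:
            raise ValueError("Tanimoto similarity must be in [0, 1]")


def parse_structure(structure: str) -> Chem.Mol:
    """Parse SMILES text or a MOL block into an RDKit molecule."""
    text = structure.strip()
    mol = None
    if "\n" in text or "M  END" in text:
        mol = Chem.MolFromMolBlock(structure)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise StructureError(f"could not parse structure: {structure[:60]!r}")
    return mol


def compute_descriptor_matrix(structures: Sequence[str]) -> np.ndarray:
    """Standardized 2-D descriptor matrix (components x descriptors).

    Descriptors that are undefined (non-finite) for any molecule or
    constant across the set are dropped before standardization to zero
    mean / unit variance.
    """
    if len(structures) < 3:
        raise ValueError("the clustering path needs at least 3 structures")
    rows = []
    for i, s in enumerate(structures):
        try:
            mol = parse_structure(s)
        except StructureError as err:
            raise StructureError(f"component {i}: {err}") from None
        rows.append(Descriptors.CalcMolDescriptors(mol))
    names = sorted(rows[0])
    mat = np.array([[float(r[n]) for n in names] for r in rows], dtype=float)
    finite = np.all(np.isfinite(mat), axis=0)
    mat = mat[:, finite]
    sd = mat.std(axis=0, ddof=0)
    keep = sd > 0
    mat = mat[:, keep]
    if mat.shape[1] == 0:
        raise ValueError("no informative descriptors (all rows identical?)")
    return (mat - mat.mean(axis=0)) / mat.std(axis=0, ddof=0)


def pca_reduce(matrix: np.ndarray, var_threshold: float = 0.95) -> np.ndarray:
    """PCA scores keeping the fewest components reaching ``var_threshold``
    cumulative explained variance; deterministic sign (largest-magnitude
    loading positive per component)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 3:
        raise ValueError("PCA grouping needs at least 3 rows")
    if np.allclose(matrix, matrix[0]):
        raise ValueError("degenerate input: all rows identical")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(matrix)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_pcs = int(np.searchsorted(cum, var_threshold) + 1)
    n_pcs = min(n_pcs, scores.shape[1])
    scores = scores[:, :n_pcs].copy()
    for j in range(n_pcs):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return scores


def cluster_moa(scores: np.ndarray, k: int, seed: int = DEFAULT_CLUSTER_SEED) -> np.ndarray:
    """Seeded k-means labels, renumbered by first occurrence."""
    n = scores.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must be in [2, n-1] = [2, {n - 1}], got {k}")
    km = KMeans(n_clusters=k, n_init=25, random_state=seed)
    raw = km.fit_predict(scores)
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[i] = remap[lab]
    return labels


def select_k(
    scores: np.ndarray,
    k_max: int = 8,
    seed: int = DEFAULT_CLUSTER_SEED,
) -> int:
    """Smallest k maximizing the mean silhouette over k in {2..min(n-1, k_max)}."""
    n = scores.shape[0]
    best_k, best_s = 2, -np.inf
    for k in range(2, min(n - 1, k_max) + 1):
        labels = cluster_moa(scores, k, seed)
        s = silhouette_score(scores, labels)
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    return best_k


def ecfp6_tanimoto(structure_a: str, structure_b: str) -> float:
    """Tanimoto similarity of diameter-6 (radius-3) 2048-bit Morgan
    fingerprints; symmetric, 1.0 iff the bit sets are identical."""
    fa = _MORGAN.GetFingerprint(parse_structure(structure_a))
    fb = _MORGAN.GetFingerprint(parse_structure(structure_b))
    from rdkit import DataStructs

    return float(DataStructs.TanimotoSimilarity(fa, fb))


def binary_moa_rule(similarity: float) -> str:
    """CA for structural similarity strictly above 0.7 (similar MoA
    assumed), IA otherwise."""
    if not 0 <= similarity <= 1:
        raise ValueError(f"similarity must be in [0, 1], got {similarity}")
    return "CA" if similarity > SIMILARITY_THRESHOLD else "IA"


def cluster_mixture(
    spec: MixtureSpec,
    k: int | None = None,
    seed: int = DEFAULT_CLUSTER_SEED,
    var_threshold: float = 0.95,
) -> MoAClustering:
    """Full MoA grouping for a spec with structures.

    Binary mixtures use the ECFP6 Tanimoto rule; larger mixtures run the
    descriptors -> PCA -> k-means pipeline (k by silhouette unless given).
    """
    structures = []
    for comp in spec.components:
        if comp.structure is None:
            raise ValueError(f"component {comp.name!r} has no structure")
        structures.append(comp.structure)
    n = len(structures)
    if n == 2:
        sim = ecfp6_tanimoto(*structures)
        choice = binary_moa_rule(sim)
        labels = (0, 0) if choice == "CA" else (0, 1)
        return MoAClustering(2, labels, seed=seed,
                             binary_similarity=sim, binary_choice=choice)
    mat = compute_descriptor_matrix(structures)
    scores = pca_reduce(mat, var_threshold)
    if k is None:
        k = select_k(scores, seed=seed)
    labels = cluster_moa(scores, k, seed)
    sil = float(silhouette_score(scores, labels)) if k >= 2 else None
    pca_full = PCA(svd_solver="full").fit(mat)
    expl = float(np.cumsum(pca_full.explained_variance_ratio_)[scores.shape[1] - 1])
    return MoAClustering(
        n, tuple(int(v) for v in labels),
        descriptor_dim=mat.shape[1], n_pcs=scores.shape[1], k=k, seed=seed,
        silhouette=sil, explained_variance=expl,
    )


# ---------------------------------------------------------------------------
# Two-stage prediction: CA within clusters, IA across clusters

def _cluster_groups(spec: MixtureSpec, clustering: MoAClustering):
    groups: dict[int, list] = {}
    for comp, lab in zip(spec.components, clustering.labels):
        groups.setdefault(int(lab), []).append(comp)
    return groups


def tsp_effect(spec: MixtureSpec, clustering: MoAClustering, conc: float) -> float:
    """Mixture effect at ``conc``: stage 1 is CA (generalized form) within
    each cluster at the cluster's share of the dose; stage 2 multiplies the
    cluster non-responses (IA)."""
    if not conc > 0:
        raise ValueError(f"concentration must be > 0, got {conc}")
    groups = _cluster_groups(spec, clustering)
    unit = spec.output_unit
    non_response = 1.0
    for comps in groups.values():
        p_g = sum(c.fraction for c in comps)
        from dataclasses import replace

        scaled = [replace(c, fraction=c.fraction / p_g) for c in comps]
        if len(scaled) == 1:
            from .mixture import _component_effect

            e_g = _component_effect(scaled[0], p_g * conc, unit)
        else:
            try:
                e_g = gca_effect(scaled, p_g * conc, unit)
            except EffectUnattainableError:
                e_g = min(c.drc.max_effect for c in scaled)
        non_response *= 1.0 - e_g
    return 1.0 - non_response


def tsp_effective_concentration(
    spec: MixtureSpec, clustering: MoAClustering, effect: float
) -> float:
    """Numeric inversion of :func:`tsp_effect` on log10(concentration)."""
    if clustering is None:
        raise ValueError("TSP requires a MoA clustering")
    if not 0 < effect < 1:
        raise ValueError(f"effect must be in (0, 1), got {effect}")
    groups = _cluster_groups(spec, clustering)
    sup = 1.0
    for comps in groups.values():
        # a cluster's supremum effect under generalized CA is bounded by its
        # most efficacious member
        sup_g = max(c.drc.max_effect for c in comps)
        sup *= 1.0 - sup_g
    sup = 1.0 - sup
    if effect >= sup:
        raise EffectUnattainableError(
            f"effect {effect:.4g} exceeds the TSP supremum {sup:.4g}"
        )
    f = lambda t: tsp_effect(spec, clustering, 10.0**t) - effect
    lo, hi = -9.0, 9.0
    for _ in range(40):
        if f(lo) <= 0:
            break
        lo -= 9.0
    for _ in range(40):
        if f(hi) >= 0:
            break
        hi += 9.0
    if f(hi) < 0:
        raise EffectUnattainableError(
            f"effect {effect:.4g} not reached by TSP at any finite concentration"
        )
    t = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=300)
    return float(10.0**t)
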
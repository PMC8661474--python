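"""Edge filtering, mediator-centric pruning and candidate extraction.

From the Spearman and NRR matrices the network is assembled in three
steps:

1. **filter_nonspurious** — keep unordered pairs whose NRR is at or below
   the threshold (default 0.1, inclusive);
2. **prune_lipid_lipid** — drop edges between two lipids, keeping the
   network centred on the inflammatory mediators;
3. **strong_candidates** — among the surviving mediator-involved edges,
   keep those with |rho| at or above the strong threshold (default 0.5,
   inclusive) as the consistent disease-associated candidates.

:class:`SpearmanNRRNetwork` wraps the whole chain (including the
association matrices) as a scikit-learn estimator fitted on a fold-change
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .association import (
    CorrelationMatrix,
    NRRConfig,
    NRRMatrix,
    nrr_histogram,
    nrr_matrix,
    spearman_matrix,
)
from .io import MEDIATOR_ROLES, FeatureCatalog, ValidationError
from .preprocess import FoldChangeMatrix

EDGE_KINDS = ("mediator-mediator", "mediator-lipid", "lipid-lipid")


@dataclass(frozen=True)
class EdgeRecord:
    """A retained, non-spurious association between two features.

    Canonical form: feature_a < feature_b lexicographically.
    """

    feature_a: str
    feature_b: str
    rho: float
    nrr: float
    kind: str

    def __post_init__(self) -> None:
        if self.feature_a >= self.feature_b:
            raise ValidationError(
                f"edge endpoints not in canonical order: {self.feature_a!r} >= {self.feature_b!r}"
            )
        if self.kind not in EDGE_KINDS:
            raise ValidationError(f"unknown edge kind {self.kind!r}")


@dataclass(frozen=True)
class CandidateRecord:
    """A strong mediator-involved association (|rho| >= threshold)."""

    mediator: str
    lipid: str
    rho: float
    nrr: float
    group_difference_p: float | None = None
    significant_group_difference: bool | None = None


# ---------------------------------------------------------------------------
# operations


def filter_nonspurious(
    rho: CorrelationMatrix,
    nrr: NRRMatrix,
    threshold: float = 0.1,
    catalog: FeatureCatalog | None = None,
) -> list[EdgeRecord]:
    """Retain exactly the unordered pairs with NRR <= threshold (inclusive).

    Edge kind is classified from the catalog when one is given; without a
    catalog roles are unknown and every edge is labelled "mediator-lipid",
    so pass a catalog whenever kinds matter downstream (pruning, candidate
    extraction).
    """
    if rho.feature_ids != nrr.feature_ids:
        raise ValidationError("rho and nrr matrices have mismatched feature lists")
    if not 0 <= threshold <= 1:
        raise ValidationError(f"NRR threshold must be in [0,1], got {threshold}")
    ids = rho.feature_ids
    edges = []
    p = len(ids)
    for i in range(p):
        for j in range(i + 1, p):
            if nrr.nrr[i, j] <= threshold:
                a, b = sorted((ids[i], ids[j]))
                kind = catalog.edge_kind(a, b) if catalog is not None else "mediator-lipid"
                edges.append(
                    EdgeRecord(a, b, float(rho.rho[i, j]), float(nrr.nrr[i, j]), kind)
                )
    return edges


def prune_lipid_lipid(
    edges: Sequence[EdgeRecord], catalog: FeatureCatalog
) -> list[EdgeRecord]:
    """Drop lipid-lipid edges; every surviving edge touches >= 1 mediator."""
    for e in edges:
        for f in (e.feature_a, e.feature_b):
            if f not in catalog:
                raise ValidationError(f"edge endpoint {f!r} not in catalog")
    return [e for e in edges if catalog.edge_kind(e.feature_a, e.feature_b) != "lipid-lipid"]


def build_network(edges: Sequence[EdgeRecord], catalog: FeatureCatalog) -> nx.Graph:
    """Assemble the signed, magnitude-weighted association graph.

    Nodes are the features incident to at least one retained edge (isolated
    features are omitted), attributed with their role and lipid class; each
    edge carries rho, nrr, weight = |rho| and sign = sign(rho).
    """
    g = nx.Graph()
    for e in edges:
        for f in (e.feature_a, e.feature_b):
            if f not in g:
                g.add_node(f, role=catalog.role(f), lipid_class=catalog.lipid_class(f))
        g.add_edge(
            e.feature_a,
            e.feature_b,
            rho=float(e.rho),
            nrr=float(e.nrr),
            weight=abs(float(e.rho)),
            sign=int(np.sign(e.rho)),
            kind=e.kind,
        )
    return g


def strong_candidates(
    edges: Sequence[EdgeRecord],
    rho_threshold: float = 0.5,
    include_mediator_mediator: bool = False,
) -> list[CandidateRecord]:
    """Keep mediator-involved edges with |rho| >= rho_threshold (inclusive).

    By default only mediator-lipid pairs are reported (the candidate table
    is about lipid biomarkers); mediator-mediator pairs can be included
    with a flag. Records are sorted by |rho| descending.
    """
    kinds = {"mediator-lipid"} | (
        {"mediator-mediator"} if include_mediator_mediator else set()
    )
    out = [
        CandidateRecord(e.feature_a, e.feature_b, e.rho, e.nrr)
        for e in edges
        if e.kind in kinds and abs(e.rho) >= rho_threshold
    ]
    # endpoints are in canonical lexicographic order here; orient_candidates
    # puts the mediator in the mediator slot once a catalog is available
    out.sort(key=lambda c: (-abs(c.rho), c.mediator, c.lipid))
    return out


def orient_candidates(
    candidates: Sequence[CandidateRecord], catalog: FeatureCatalog
) -> list[CandidateRecord]:
    """Return candidates with the mediator endpoint in the mediator slot."""
    fixed = []
    for c in candidates:
        med, lip = c.mediator, c.lipid
        if lip in catalog and catalog.is_mediator(lip) and not (
            med in catalog and catalog.is_mediator(med)
        ):
            med, lip = lip, med
        fixed.append(
            CandidateRecord(
                med, lip, c.rho, c.nrr, c.group_difference_p, c.significant_group_difference
            )
        )
    return fixed


# ---------------------------------------------------------------------------
# scikit-learn estimator


class SpearmanNRRNetwork(BaseEstimator):
    """NRR-filtered Spearman association network, as a sklearn estimator.

    ``fit`` takes a fold-change matrix X (pairs x features) and computes the
    Spearman matrix, the NRR matrix, the filtered + pruned edge list, the
    graph and the strong-candidate list as fitted attributes.

    Parameters
    ----------
    nrr_threshold : retain pairs with NRR <= this value (inclusive).
    rho_threshold : strong-candidate |rho| cutoff (inclusive).
    alpha, n_tests, q_policy, q, q_max, mode : NRR test configuration, see
        :class:`~nrrnet.association.NRRConfig`.
    random_state : master seed for the conditioning-set sampling.
    catalog : optional FeatureCatalog; required for lipid-lipid pruning and
        for candidate role orientation. Without it, no edges are pruned and
        every edge is treated as mediator-involved.
    """

    def __init__(
        self,
        nrr_threshold: float = 0.1,
        rho_threshold: float = 0.5,
        alpha: float = 0.05,
        n_tests: int = 100,
        q_policy: str = "uniform",
        q: int | None = None,
        q_max: int | None = None,
        mode: str = "monte_carlo",
        random_state: int = 0,
        catalog: FeatureCatalog | None = None,
    ):
        self.nrr_threshold = nrr_threshold
        self.rho_threshold = rho_threshold
        self.alpha = alpha
        self.n_tests = n_tests
        self.q_policy = q_policy
        self.q = q
        self.q_max = q_max
        self.mode = mode
        self.random_state = random_state
        self.catalog = catalog

    def _nrr_config(self) -> NRRConfig:
        return NRRConfig(
            alpha=self.alpha,
            n_tests=self.n_tests,
            q_policy=self.q_policy,
            q=self.q,
            q_max=self.q_max,
            mode=self.mode,
            seed=int(self.random_state),
        )

    def fit(self, X, y=None):
        if isinstance(X, FoldChangeMatrix):
            frame = X.to_frame()
        elif isinstance(X, pd.DataFrame):
            frame = X
        else:
            arr = check_array(X)
            frame = pd.DataFrame(arr, columns=[f"f{i}" for i in range(arr.shape[1])])
        check_array(frame.to_numpy(float))
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        self.rho_ = spearman_matrix(frame)
        self.nrr_ = nrr_matrix(frame, self._nrr_config())
        self.histogram_ = nrr_histogram(self.nrr_)
        edges = filter_nonspurious(
            self.rho_, self.nrr_, self.nrr_threshold, catalog=self.catalog
        )
        if self.catalog is not None:
            edges = prune_lipid_lipid(edges, self.catalog)
        self.edges_ = edges
        cands = strong_candidates(edges, self.rho_threshold)
        if self.catalog is not None:
            cands = orient_candidates(cands, self.catalog)
            self.graph_ = build_network(edges, self.catalog)
        self.candidates_ = cands
        return self

    def transform(self, X=None) -> pd.DataFrame:
        """Fitted edge list as a DataFrame (feature_a, feature_b, rho, nrr, kind)."""
        check_is_fitted(self)
        return pd.DataFrame(
            [(e.feature_a, e.feature_b, e.rho, e.nrr, e.kind) for e in self.edges_],
            columns=["feature_a", "feature_b", "rho", "nrr", "kind"],
        )
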
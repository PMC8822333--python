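"""Pathway enrichment directly on m/z features (mummichog-style).

Features are annotated to candidate compounds through positive-mode adduct
mass rules (M[1+], M+H[1+], M+Na[1+]) at a ppm tolerance, features collapse
to unique compounds, and each pathway is tested with a right-tail
hypergeometric (Fisher) p-value of the overlap between the significant
compound list and the pathway within the annotated reference. An empirical
permutation p-value resamples significant-sized feature lists from the
reference with the add-one estimator (1 + #{perm <= obs}) / (1 + B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .synthetic import ADDUCT_DELTAS, CompoundDB


@dataclass(frozen=True)
class AdductRule:
    name: str
    mass_delta: float
    charge: int = 1


DEFAULT_ADDUCTS = tuple(
    AdductRule(name, delta) for name, delta in ADDUCT_DELTAS.items()
)


def annotate_features_mz(
    mz_values: pd.Series | dict[str, float],
    db: CompoundDB,
    adducts: tuple[AdductRule, ...] = DEFAULT_ADDUCTS,
    tol_ppm: float = 10.0,
) -> pd.DataFrame:
    """Match each feature m/z to candidate compounds under the adduct rules.

    A feature matches compound c under adduct a iff
    |mz - (mass_c + delta_a)| / (mass_c + delta_a) * 1e6 <= tol_ppm.
    Returns rows (feature, compound, adduct, ppm_error); all matches kept.
    """
    if isinstance(mz_values, dict):
        mz_values = pd.Series(mz_values)
    if tol_ppm <= 0:
        raise ConfigurationError("tol_ppm must be positive")
    masses = db.compounds["mass"].to_numpy(dtype=float)
    cids = db.compounds["compound_id"].to_numpy()
    rows = []
    for adduct in adducts:
        theo = masses + adduct.mass_delta
        order = np.argsort(theo)
        theo_sorted = theo[order]
        for fid, mz in mz_values.items():
            tol = theo_sorted * tol_ppm * 1e-6
            lo = np.searchsorted(theo_sorted, mz - tol.max())
            hi = np.searchsorted(theo_sorted, mz + tol.max())
            for k in range(lo, hi):
                ppm = abs(mz - theo_sorted[k]) / theo_sorted[k] * 1e6
                if ppm <= tol_ppm:
                    rows.append((fid, cids[order[k]], adduct.name, float(ppm)))
    return pd.DataFrame(rows, columns=["feature", "compound", "adduct", "ppm_error"])


def _compounds_of(annotation: pd.DataFrame, features) -> set[str]:
    sub = annotation[annotation["feature"].isin(set(features))]
    return set(sub["compound"])


def fisher_enrichment(
    significant_compounds: set[str],
    reference_compounds: set[str],
    db: CompoundDB,
) -> pd.DataFrame:
    """Right-tail hypergeometric p per pathway on unique compounds.

    N = reference size, K = pathway compounds within the reference,
    n = significant compounds, k = overlap; p = P(X >= k),
    X ~ Hypergeom(N, K, n). Pathways absent from the reference are skipped.
    """
    significant = set(significant_compounds) & set(reference_compounds)
    N = len(reference_compounds)
    n = len(significant)
    rows = []
    for pid, members in db.pathways.items():
        ref_members = members & set(reference_compounds)
        K = len(ref_members)
        if K == 0:
            continue
        k = len(significant & ref_members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((pid, db.pathway_names.get(pid, pid), k, K, n, N, p))
    return pd.DataFrame(
        rows,
        columns=["pathway", "pathway_name", "k", "K", "n", "N", "fisher_p"],
    ).sort_values("fisher_p", kind="stable").reset_index(drop=True)


def permutation_adjust(
    observed: pd.DataFrame,
    reference_features: list[str],
    annotation: pd.DataFrame,
    db: CompoundDB,
    n_sig_features: int,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical permutation p per pathway by resampling feature lists.

    Each permutation draws ``n_sig_features`` features from the reference,
    annotates them, and recomputes every pathway's Fisher p; then
    permutation_p = (1 + #{perm p <= observed p}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    reference_features = list(reference_features)
    ref_compounds = _compounds_of(annotation, reference_features)
    perm_ps: dict[str, list[float]] = {pid: [] for pid in observed["pathway"]}
    n_draw = min(n_sig_features, len(reference_features))
    for _ in range(n_perm):
        draw = rng.choice(reference_features, size=n_draw, replace=False)
        sig = _compounds_of(annotation, draw)
        perm = fisher_enrichment(sig, ref_compounds, db)
        lookup = dict(zip(perm["pathway"], perm["fisher_p"]))
        for pid in perm_ps:
            perm_ps[pid].append(lookup.get(pid, 1.0))
    out = observed.copy()
    pvals = []
    for pid, obs_p in zip(out["pathway"], out["fisher_p"]):
        hits = sum(1 for q in perm_ps[pid] if q <= obs_p)
        pvals.append((1.0 + hits) / (1.0 + n_perm))
    out["permutation_p"] = pvals
    return out


def enrich_cluster(
    community_features: list[str],
    all_features: list[str],
    db: CompoundDB,
    mz_values: pd.Series,
    adducts: tuple[AdductRule, ...] = DEFAULT_ADDUCTS,
    tol_ppm: float = 10.0,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, str]:
    """Enrichment of one community against the full clean feature list.

    Significant list = the community's features annotated to compounds;
    reference = all clean features annotated. Returns the per-pathway table
    (Fisher + permutation p) and a status string; clusters with no compound
    matches return an empty table with status "no pathway mapping".
    """
    community_features = list(community_features)
    missing = set(community_features) - set(all_features)
    if missing:
        raise ConfigurationError(
            f"{len(missing)} community features are not in the clean feature list"
        )
    annotation = annotate_features_mz(mz_values, db, adducts, tol_ppm)
    sig_compounds = _compounds_of(annotation, community_features)
    ref_compounds = _compounds_of(annotation, all_features)
    if not sig_compounds:
        empty = pd.DataFrame(
            columns=["pathway", "pathway_name", "k", "K", "n", "N",
                     "fisher_p", "permutation_p"]
        )
        return empty, "no pathway mapping"
    observed = fisher_enrichment(sig_compounds, ref_compounds, db)
    result = permutation_adjust(
        observed,
        reference_features=all_features,
        annotation=annotation,
        db=db,
        n_sig_features=len(community_features),
        n_perm=n_perm,
        seed=seed,
    )
    return result, "ok"
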
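"""Module-quality evaluation.

Identified md-modules are scored against gold standards with the
relevance score: for each identified module take the best Jaccard
similarity against any gold module, then average over the identified
modules.  Member identifiers are namespaced by role (``sample:...``,
``X:...``, ``Y:...``) so that sample recovery and feature recovery both
enter the score; a features-only mode restricts the comparison to
feature members.

The module also provides sample-wise correlations between original and
reconstructed data for factorization fits, and the simulation-study
harness comparing the NMF and PLS routes across noise levels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import MethodParams
from .modules import ModuleSet, MdModule, extract_modules_nmf, extract_modules_pls
from .nmf import FactorizationResult, fit_jnmf
from .pls import LatentComponentSet, fit_multiblock
from .preprocess import nonneg_split

__all__ = [
    "GoldStandard",
    "jaccard",
    "module_member_ids",
    "relevance_score",
    "best_match",
    "reconstruction_correlation",
    "run_jnmf_on_bundle",
    "run_smbpls_on_bundle",
    "compare_methods",
    "write_gold_standard",
    "read_gold_standard",
]


@dataclass
class GoldStandard:
    """Reference member sets for embedded co-modules.

    ``standard_id`` names the archetype the standard encodes: ``"NMF"``
    for high-absolute-signal members, ``"PLS"`` for strongly correlated
    members.  Each module is a frozenset of namespaced identifiers.
    """

    standard_id: str
    modules: list[frozenset[str]]

    def __post_init__(self) -> None:
        if not self.modules:
            raise ValueError("a gold standard needs at least one module")
        self.modules = [frozenset(m) for m in self.modules]

    def restrict(self, features_only: bool) -> list[frozenset[str]]:
        if not features_only:
            return self.modules
        return [
            frozenset(x for x in mod if not x.startswith("sample:")) for mod in self.modules
        ]


def jaccard(a: set[str] | frozenset[str], b: set[str] | frozenset[str]) -> float:
    """|a & b| / |a | b|; two empty sets score 0 (empty modules earn nothing)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def module_member_ids(module: MdModule, features_only: bool = False) -> frozenset[str]:
    """Namespaced identifier set of one identified module."""
    ids = {f"{ftype}:{label}" for ftype, members in module.members.items() for label in members}
    if not features_only:
        ids |= {f"sample:{s}" for s in module.samples}
    return frozenset(ids)


def best_match(
    module: MdModule, gold: GoldStandard, features_only: bool = False
) -> tuple[int, float]:
    """Index and Jaccard of the gold module best matching ``module``."""
    ids = module_member_ids(module, features_only)
    scores = [jaccard(ids, g) for g in gold.restrict(features_only)]
    best = int(np.argmax(scores))
    return best, scores[best]


def relevance_score(
    modules: ModuleSet, gold: GoldStandard, features_only: bool = False
) -> float:
    """Mean best-Jaccard of the identified modules against the standard.

    Every identified module is matched independently to its best gold
    module (no one-to-one assignment), and the matches are averaged;
    the score is 1 exactly when every identified module coincides with
    some gold module.
    """
    if len(modules) == 0:
        raise ValueError("cannot score an empty ModuleSet")
    return float(np.mean([best_match(mod, gold, features_only)[1] for mod in modules]))


def reconstruction_correlation(
    X_blocks: list[np.ndarray],
    result: FactorizationResult,
    sample_labels: list[str] | None = None,
    block_names: list[str] | None = None,
) -> pd.DataFrame:
    """Sample-wise correlation between each block and its reconstruction.

    For every block i and sample (row) r, the Pearson correlation
    between ``X_i[r]`` and ``(W H_i)[r]``.  Rows with zero variance on
    either side have no defined correlation and are reported as NaN
    with ``defined = False``.
    """
    if len(X_blocks) != len(result.H_list):
        raise ValueError("one data block per coefficient matrix is required")
    m = X_blocks[0].shape[0]
    if sample_labels is None:
        sample_labels = [str(i) for i in range(m)]
    if block_names is None:
        block_names = [f"block{i + 1}" for i in range(len(X_blocks))]
    rows = []
    for name, X, Hi in zip(block_names, X_blocks, result.H_list):
        R = result.W @ Hi
        for r in range(m):
            x, y = X[r], R[r]
            if x.std() == 0 or y.std() == 0:
                rows.append({"block": name, "sample": sample_labels[r],
                             "correlation": np.nan, "defined": False})
            else:
                rows.append({"block": name, "sample": sample_labels[r],
                             "correlation": float(np.corrcoef(x, y)[0, 1]), "defined": True})
    return pd.DataFrame(rows, columns=["block", "sample", "correlation", "defined"])


# ---------------------------------------------------------------------------
# simulation-study harness


def run_jnmf_on_bundle(bundle, params: MethodParams) -> tuple[ModuleSet, FactorizationResult]:
    """Fit jNMF to one simulated bundle and extract its md-modules.

    Both matrices contain negative entries, so each is expanded by the
    positive/negative split before the non-negative fit; module
    members are reported against the original features.
    """
    splits = [nonneg_split(bundle.X), nonneg_split(bundle.Y)]
    result = fit_jnmf([s.data for s in splits], params)
    modules = extract_modules_nmf(
        result,
        bundle.sample_labels,
        [bundle.x_labels, bundle.y_labels],
        ["X", "Y"],
        thrd_module=params.thrd_module,
        splits=splits,
    )
    return modules, result


def run_smbpls_on_bundle(bundle, params: MethodParams) -> tuple[ModuleSet, LatentComponentSet]:
    """Fit sMBPLS to one simulated bundle and extract its md-modules."""
    result = fit_multiblock("smbpls", [bundle.X], bundle.Y, params)
    modules = extract_modules_pls(
        result,
        bundle.sample_labels,
        [bundle.x_labels],
        ["X"],
        bundle.y_labels,
        "Y",
        sample_threshold=params.sample_threshold,
    )
    return modules, result


def compare_methods(
    noise_grid: list[float],
    n_replicates: int,
    seed: int,
    base_config=None,
    jnmf_params: MethodParams | None = None,
    smbpls_params: MethodParams | None = None,
) -> pd.DataFrame:
    """Relevance of jNMF and sMBPLS across noise levels and replicates.

    For each noise level and replicate a fresh data set is generated,
    both methods are fitted with k equal to the number of embedded
    co-modules, modules are extracted, and each method is scored
    against both gold standards.  Returns the long table of scores
    (columns: noise, replicate, method, standard, relevance).
    """
    from dataclasses import replace

    from .simulate import SimulationConfig, replicate_grid

    if base_config is None:
        base_config = SimulationConfig()
    base_config = replace(base_config, seed=seed)
    if jnmf_params is None:
        jnmf_params = MethodParams(n_modules=5, n_restarts=5, seed=seed)
    if smbpls_params is None:
        smbpls_params = MethodParams(n_modules=5, seed=seed)

    bundles = replicate_grid(base_config, noise_grid, n_replicates)
    rows = []
    for idx, bundle in enumerate(bundles):
        noise = bundle.config.noise_sd
        rep = idx % n_replicates
        fit_seed = bundle.config.seed
        nmf_modules, _ = run_jnmf_on_bundle(bundle, replace(jnmf_params, seed=fit_seed))
        pls_modules, _ = run_smbpls_on_bundle(bundle, replace(smbpls_params, seed=fit_seed))
        for method, modules in (("jnmf", nmf_modules), ("smbpls", pls_modules)):
            for gold in (bundle.G1, bundle.G2):
                rows.append(
                    {
                        "noise": noise,
                        "replicate": rep,
                        "method": method,
                        "standard": gold.standard_id,
                        "relevance": relevance_score(modules, gold),
                    }
                )
    return pd.DataFrame(rows, columns=["noise", "replicate", "method", "standard", "relevance"])


def simulation_recovery_counts(bundle, modules: ModuleSet) -> dict:
    """Member-recovery counts for the two narrated co-modules.

    For embedded co-module 2 (the sample-split correlation module): the
    number of its full (correlation-standard) sample set found in the
    identified module that best matches it.  For embedded co-module 1:
    the number of response features from its correlated block (the
    first third of Y's columns, i.e. columns 1-100 at default sizes)
    found in the best-matching identified module.  Matching is by
    highest Jaccard against the correlation-standard member sets.
    """
    best_for = {}
    for k in (0, 1):
        gold = bundle.G2.modules[k]
        best_for[k] = max(modules, key=lambda m: jaccard(module_member_ids(m), gold))
    gold2_samples = {x for x in bundle.G2.modules[1] if x.startswith("sample:")}
    found_samples = {f"sample:{s}" for s in best_for[1].samples}
    corr_block = bundle.module_specs[0].pieces  # module 1's correlated Y range
    y_corr = set()
    for piece in corr_block:
        if piece.matrix == "Y" and piece.correlated:
            y_corr.update(f"Y:{bundle.y_labels[j]}" for j in piece.rng.indices)
    found_y = {f"Y:{label}" for label in best_for[0].members.get("Y", set())}
    return {
        "comodule2_samples": len(found_samples & gold2_samples),
        "comodule1_y_features": len(found_y & y_corr),
    }


# ---------------------------------------------------------------------------
# gold standard files


def write_gold_standard(gold: GoldStandard, path: str | os.PathLike) -> None:
    """TSV with one member per line: module_id, role, label."""
    rows = []
    for k, module in enumerate(gold.modules, start=1):
        for ident in sorted(module):
            role, label = ident.split(":", 1)
            rows.append({"module_id": k, "role": role, "label": label})
    pd.DataFrame(rows, columns=["module_id", "role", "label"]).to_csv(
        os.fspath(path), sep="\t", index=False
    )


def read_gold_standard(path: str | os.PathLike, standard_id: str = "NMF") -> GoldStandard:
    table = pd.read_csv(os.fspath(path), sep="\t")
    required = {"module_id", "role", "label"}
    if not required.issubset(table.columns):
        raise ValueError(f"gold standard file must have columns {sorted(required)}")
    modules = []
    for _, grp in table.groupby("module_id"):
        modules.append(
            frozenset(f"{r}:{l}" for r, l in zip(grp["role"].astype(str), grp["label"].astype(str)))
        )
    return GoldStandard(standard_id, modules)
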
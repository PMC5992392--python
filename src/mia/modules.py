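"""Conversion of factorization output into md-modules.

An md-module is a set of samples together with a set of member
features from each data type that share one coherent pattern.  For the
NMF family, factor f yields one module: the samples whose basis
loading ``W[:, f]`` exceeds ``mean + T0 * sd`` of that column, and per
block the features whose coefficient ``H_i[f, :]`` exceeds
``mean + T_i * sd`` of that row (larger thresholds select fewer
members).  For the PLS family, component c yields one module: the
features in the supports of the sparse weight vectors, plus the
samples whose |super score| stands out against the bulk of samples.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nmf import FactorizationResult
from .pls import LatentComponentSet
from .preprocess import NonnegSplit

__all__ = ["MdModule", "ModuleSet", "extract_modules_nmf", "extract_modules_pls",
           "module_stats", "module_size_summary"]


@dataclass
class MdModule:
    """Member sets of one multi-dimensional module."""

    module_id: int
    samples: set[str]
    members: dict[str, set[str]]
    source: str
    thresholds_used: dict
    member_signs: dict[str, dict[str, str]] = field(default_factory=dict)

    def member_count(self) -> dict[str, int]:
        out = {"sample": len(self.samples)}
        out.update({ftype: len(s) for ftype, s in self.members.items()})
        return out


@dataclass
class ModuleSet:
    """All md-modules extracted from one fitted model."""

    modules: list[MdModule]
    method: str
    feature_types: list[str]

    def __post_init__(self) -> None:
        ids = [m.module_id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise ValueError("module_id values must be unique within a ModuleSet")

    def __iter__(self):
        return iter(self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def to_member_table(self) -> pd.DataFrame:
        rows = []
        for mod in self.modules:
            for label in sorted(mod.samples):
                rows.append({"module_id": mod.module_id, "member_type": "sample",
                             "label": label, "sign": "+"})
            for ftype in self.feature_types:
                signs = mod.member_signs.get(ftype, {})
                for label in sorted(mod.members.get(ftype, set())):
                    rows.append({"module_id": mod.module_id, "member_type": ftype,
                                 "label": label, "sign": signs.get(label, "+")})
        return pd.DataFrame(rows, columns=["module_id", "member_type", "label", "sign"])

    @classmethod
    def from_member_table(cls, table: pd.DataFrame, method: str = "unknown") -> "ModuleSet":
        feature_types = [t for t in table["member_type"].unique() if t != "sample"]
        modules = []
        for mid, grp in table.groupby("module_id"):
            samples = set(grp.loc[grp["member_type"] == "sample", "label"].astype(str))
            members = {
                ftype: set(grp.loc[grp["member_type"] == ftype, "label"].astype(str))
                for ftype in feature_types
            }
            modules.append(MdModule(int(mid), samples, members, source=method,
                                    thresholds_used={}))
        return cls(modules=modules, method=method, feature_types=list(feature_types))

    def write_member_lists(self, directory: str | os.PathLike) -> None:
        """One folder per member type (``<FeatureType>Lists``), one file
        per module with one member label per line."""
        directory = os.fspath(directory)
        for ftype in ["Sample"] + self.feature_types:
            folder = os.path.join(directory, f"{ftype}Lists")
            os.makedirs(folder, exist_ok=True)
            for mod in self.modules:
                labels = mod.samples if ftype == "Sample" else mod.members.get(ftype, set())
                path = os.path.join(folder, f"module_{mod.module_id:02d}.txt")
                with open(path, "w") as fh:
                    fh.write("\n".join(sorted(labels)) + ("\n" if labels else ""))


def _threshold_select(values: np.ndarray, t: float) -> np.ndarray:
    """Indices with value above ``mean + t * sd`` of the vector."""
    cut = values.mean() + t * values.std()
    return np.flatnonzero(values > cut)


def extract_modules_nmf(
    result: FactorizationResult,
    sample_labels: list[str],
    block_feature_labels: list[list[str]],
    feature_types: list[str],
    thrd_module: list[float] | None = None,
    splits: list[NonnegSplit | None] | None = None,
) -> ModuleSet:
    """One md-module per factor of a fitted NMF model.

    ``thrd_module`` holds ``1 + n_blocks`` non-negative thresholds: the
    first selects samples from the columns of W, the i+1-th selects
    block-i features from the rows of ``H_i``.  When a block was
    expanded by the positive/negative split, ``splits[i]`` maps the
    expanded columns back: a feature is a member if either copy passes
    the threshold, recorded once with a sign annotation ('+', '-', or
    '+/-' when both copies pass).
    """
    n_blocks = len(result.H_list)
    if thrd_module is None:
        thrd_module = [1.0] * (1 + n_blocks)
    thrd_module = [float(t) for t in thrd_module]
    if len(thrd_module) != 1 + n_blocks:
        raise ValueError(
            f"thrd_module must have {1 + n_blocks} entries (samples + each block), "
            f"got {len(thrd_module)}"
        )
    if any(t < 0 for t in thrd_module):
        raise ValueError("thrd_module entries must be >= 0")
    if len(block_feature_labels) != n_blocks or len(feature_types) != n_blocks:
        raise ValueError("need one label list and one feature type per block")
    splits = splits or [None] * n_blocks

    sample_arr = np.asarray(sample_labels, dtype=object)
    modules = []
    for f in range(result.k):
        samples = set(sample_arr[_threshold_select(result.W[:, f], thrd_module[0])])
        members: dict[str, set[str]] = {}
        signs: dict[str, dict[str, str]] = {}
        for i, (labels, ftype) in enumerate(zip(block_feature_labels, feature_types)):
            row = result.H_list[i][f, :]
            hits = _threshold_select(row, thrd_module[i + 1])
            split = splits[i]
            chosen: set[str] = set()
            sign_map: dict[str, str] = {}
            for c in hits:
                if split is None:
                    label, sgn = labels[c], "+"
                else:
                    label = labels[int(split.origin[c])]
                    sgn = "+" if split.sign[c] > 0 else "-"
                if label in chosen and sign_map.get(label) not in (sgn, "+/-"):
                    sign_map[label] = "+/-"
                else:
                    sign_map.setdefault(label, sgn)
                chosen.add(label)
            members[ftype] = chosen
            signs[ftype] = sign_map
        modules.append(
            MdModule(
                module_id=f + 1,
                samples=samples,
                members=members,
                source=f"{result.method}:factor{f + 1}",
                thresholds_used={"thrd_module": thrd_module},
                member_signs=signs,
            )
        )
    return ModuleSet(modules=modules, method=result.method, feature_types=list(feature_types))


def extract_modules_pls(
    result: LatentComponentSet,
    sample_labels: list[str],
    block_feature_labels: list[list[str]],
    feature_types: list[str],
    response_labels: list[str],
    response_type: str,
    sample_threshold: float = 3.0,
) -> ModuleSet:
    """One md-module per extracted latent component.

    Feature members are the supports of the sparse weight vectors
    (``w_i != 0`` per predictor block, ``q != 0`` for the response);
    with zero penalties the weights are dense and every feature is a
    member, a documented degenerate case.  Sample members are chosen
    from the super score: ``|t|`` above ``median + T * 1.4826 * MAD``
    of |t|.  The robust location/scale pair treats the bulk of samples
    as background, so module samples with genuinely low — but
    coherent — signal still stand out.
    """
    sample_arr = np.asarray(sample_labels, dtype=object)
    modules = []
    for c, comp in enumerate(result.components):
        abs_t = np.abs(comp.t)
        med = float(np.median(abs_t))
        mad = float(np.median(np.abs(abs_t - med)))
        cut = med + sample_threshold * 1.4826 * mad
        samples = set(sample_arr[abs_t > cut])
        members: dict[str, set[str]] = {}
        signs: dict[str, dict[str, str]] = {}
        for i, (labels, ftype) in enumerate(zip(block_feature_labels, feature_types)):
            support = np.flatnonzero(comp.w_list[i])
            members[ftype] = {labels[j] for j in support}
            signs[ftype] = {labels[j]: ("+" if comp.w_list[i][j] > 0 else "-") for j in support}
        support = np.flatnonzero(comp.q)
        members[response_type] = {response_labels[j] for j in support}
        signs[response_type] = {
            response_labels[j]: ("+" if comp.q[j] > 0 else "-") for j in support
        }
        modules.append(
            MdModule(
                module_id=c + 1,
                samples=samples,
                members=members,
                source=f"{result.method}:component{c + 1}",
                thresholds_used={
                    "sample_threshold": sample_threshold,
                    "lambda": result.selected_lambda,
                    "mu": result.selected_mu,
                },
                member_signs=signs,
            )
        )
    return ModuleSet(
        modules=modules,
        method=result.method,
        feature_types=list(feature_types) + [response_type],
    )


def module_stats(modules: ModuleSet) -> pd.DataFrame:
    """Member counts per module and member type (long format)."""
    rows = []
    for mod in modules:
        for mtype, count in mod.member_count().items():
            rows.append({"module_id": mod.module_id, "member_type": mtype, "count": count})
    return pd.DataFrame(rows, columns=["module_id", "member_type", "count"])


def module_size_summary(stats: pd.DataFrame) -> pd.DataFrame:
    """Min / median / max module size per member type."""
    if stats.empty:
        return pd.DataFrame(columns=["member_type", "min", "median", "max"])
    agg = stats.groupby("member_type")["count"].agg(["min", "median", "max"]).reset_index()
    return agg
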
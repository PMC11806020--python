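"""Vulnerability and resilience gene sets.

Four gene sets summarize where vulnerability signal lives:

* ``SV-G`` / ``SR-G`` — the top fraction (default 10%) of genes by absolute
  mean correlation with tau across datasets, split by sign (positive =
  vulnerability, negative = resilience);
* ``SV-C`` / ``SR-C`` — unions of the most differentially expressed genes
  (row z-scores of the column-normalized signature matrix) of the vulnerable
  and resilient cell types, size-matched to the corresponding gene-based set.

A cell type counts as vulnerable when its mean correlation across datasets is
positive *and* it was selected at least once in the multivariate models; the
mirrored rule defines resilient types.  Each contributing type supplies
``ceil(|SV-G| / n_types)`` genes before deduplication, so the union lands at
or slightly above the target size.  Gene lists are exported as plain text for
external enrichment tools; no enrichment statistics are computed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GeneSignatureMatrix


@dataclass
class GeneSetCollection:
    sv_g: list[str]
    sr_g: list[str]
    sv_c: list[str]
    sr_c: list[str]
    n_ct_vuln: int
    n_ct_res: int
    n_de_vuln: int
    n_de_res: int
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, list[str]]:
        return {"SV-G": self.sv_g, "SR-G": self.sr_g,
                "SV-C": self.sv_c, "SR-C": self.sr_c}


def sv_sr_gene_sets(mean_r: pd.Series, fraction: float = 0.10
                    ) -> tuple[list[str], list[str]]:
    """Top-|mean R| genes split by sign into vulnerability and resilience sets.

    ``round(fraction * n_genes)`` genes are taken by descending absolute mean
    correlation (ties at the threshold break by gene id); positive
    correlations go to SV-G, negative to SR-G.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    clean = mean_r.dropna()
    n_top = int(np.rint(fraction * len(clean)))
    order = sorted(clean.index, key=lambda g: (-abs(clean[g]), g))
    top = order[:n_top]
    sv = sorted(g for g in top if clean[g] > 0)
    sr = sorted(g for g in top if clean[g] < 0)
    if not sr:
        warnings.warn("no anti-correlated genes in the top fraction; SR-G empty")
    if not sv:
        warnings.warn("no positively correlated genes in the top fraction; SV-G empty")
    return sv, sr


def de_zscores(C_T: pd.DataFrame) -> pd.DataFrame:
    """Row z-scores of the column-normalized signature matrix (genes x types).

    Each gene's expression is standardized across cell types with the sample
    standard deviation; zero-variance rows become all-zero and are flagged in
    ``result.attrs['degenerate_rows']``.
    """
    if C_T.shape[1] < 3:
        raise ValueError("need at least 3 cell types for differential expression")
    X = C_T.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd[:, 0] == 0
    Z = np.where(degenerate[:, None], 0.0,
                 (X - mu) / np.where(sd > 0, sd, 1.0))
    out = pd.DataFrame(Z, index=C_T.index, columns=C_T.columns)
    out.attrs["degenerate_rows"] = list(C_T.index[degenerate])
    return out


def contributing_types(mean_r_types: pd.Series, selection_counts: pd.Series,
                       direction: str = "vulnerable") -> list[str]:
    """Cell types feeding SV-C (positive mean R and selected at least once in
    multivariate models) or SR-C (the mirrored rule)."""
    if direction not in ("vulnerable", "resilient"):
        raise ValueError("direction must be 'vulnerable' or 'resilient'")
    sel = selection_counts.reindex(mean_r_types.index).fillna(0)
    if direction == "vulnerable":
        mask = (mean_r_types > 0) & (sel >= 1)
    else:
        mask = (mean_r_types < 0) & (sel >= 1)
    return sorted(mean_r_types.index[mask])


def genes_per_type(set_size: int, n_types: int) -> int:
    """Per-type DE gene budget: ``ceil(set_size / n_types)``.

    The ceiling guarantees the union can reach the target size before
    deduplication (e.g. a 277-gene target over 16 types gives 18 per type).
    """
    if n_types < 1:
        raise ValueError("need at least one contributing type")
    n = math.ceil(set_size / n_types)
    if n < 1:
        raise ValueError("per-type gene budget must be at least 1")
    return n


def cell_gene_sets(z: pd.DataFrame, types: list[str], size_match_to: int
                   ) -> tuple[list[str], int, dict[str, list[str]]]:
    """Union of each contributing type's top DE genes, size-matched to a target.

    Each type supplies its ``genes_per_type(size_match_to, len(types))`` top
    genes by z-score (ties break by gene id); the union deduplicates.
    Returns the set, the per-type budget, and the per-type contributions.
    """
    missing = set(types) - set(z.columns)
    if missing:
        raise ValueError(f"unknown types: {sorted(missing)}")
    n_per = genes_per_type(size_match_to, len(types))
    contributions: dict[str, list[str]] = {}
    union: set[str] = set()
    for t in sorted(types):
        col = z[t]
        ranked = sorted(col.index, key=lambda g: (-col[g], g))
        contributions[t] = ranked[:n_per]
        union.update(contributions[t])
    return sorted(union), n_per, contributions


def class_de_sets(C: GeneSignatureMatrix, top_n: int = 100,
                  classes: tuple[str, str] = ("cortical glutamatergic",
                                              "hippocampal glutamatergic"),
                  ) -> dict[str, list[str]]:
    """Top differentially expressed genes between two glutamatergic classes.

    z-scores are recomputed on the submatrix restricted to the two classes'
    member types; each class then collects unique genes round-robin over its
    member types' ranked gene lists until ``top_n`` genes are gathered.
    """
    members = {c: [t for t in C.type_ids if C.class_label[t] == c]
               for c in classes}
    for c, ts in members.items():
        if not ts:
            raise ValueError(f"class {c!r} has no member types")
    sub_types = [t for c in classes for t in members[c]]
    if len(sub_types) < 3:
        raise ValueError("need at least 3 types across the two classes")
    z = de_zscores(C.values[sub_types])
    out: dict[str, list[str]] = {}
    for c in classes:
        ranked_lists = []
        for t in members[c]:
            col = z[t]
            ranked_lists.append(sorted(col.index, key=lambda g: (-col[g], g)))
        collected: list[str] = []
        seen: set[str] = set()
        depth = 0
        while len(collected) < top_n and depth < len(z):
            for lst in ranked_lists:
                g = lst[depth]
                if g not in seen:
                    seen.add(g)
                    collected.append(g)
                    if len(collected) >= top_n:
                        break
            depth += 1
        out[c] = sorted(collected)
    overlap = set(out[classes[0]]) & set(out[classes[1]])
    if len(overlap) > top_n // 2:
        warnings.warn(f"heavy overlap between class DE sets ({len(overlap)} genes)")
    return out


def overlap_counts(collection: GeneSetCollection,
                   risk_genes: list[str] | None = None) -> pd.DataFrame:
    """Pairwise intersection sizes among the four sets (and a risk-gene list)."""
    sets = {k: set(v) for k, v in collection.as_dict().items()}
    if risk_genes is not None:
        sets["risk"] = set(risk_genes)
    names = list(sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rows.append({"set_a": a, "set_b": b,
                         "overlap": len(sets[a] & sets[b]),
                         "size_a": len(sets[a]), "size_b": len(sets[b])})
    return pd.DataFrame(rows)


def build_gene_sets(
    mean_r_genes: pd.Series,
    mean_r_types: pd.Series,
    selection_counts: pd.Series,
    C_T: pd.DataFrame,
    fraction: float = 0.10,
) -> GeneSetCollection:
    """Assemble the four vulnerability/resilience gene sets.

    ``mean_r_genes`` — per-gene mean correlation with tau across datasets;
    ``mean_r_types`` — same per cell type; ``selection_counts`` — how often
    each type entered a multivariate model; ``C_T`` — the column-normalized
    signature matrix used for DE z-scores.
    """
    sv_g, sr_g = sv_sr_gene_sets(mean_r_genes, fraction=fraction)
    z = de_zscores(C_T)
    vuln = contributing_types(mean_r_types, selection_counts, "vulnerable")
    res = contributing_types(mean_r_types, selection_counts, "resilient")
    if vuln and sv_g:
        sv_c, n_de_vuln, vuln_contrib = cell_gene_sets(z, vuln, len(sv_g))
    else:
        warnings.warn("no vulnerable contributing types or empty SV-G; SV-C empty")
        sv_c, n_de_vuln, vuln_contrib = [], 0, {}
    if res and sr_g:
        sr_c, n_de_res, res_contrib = cell_gene_sets(z, res, len(sr_g))
    else:
        warnings.warn("no resilient contributing types or empty SR-G; SR-C empty")
        sr_c, n_de_res, res_contrib = [], 0, {}
    return GeneSetCollection(
        sv_g=sv_g, sr_g=sr_g, sv_c=sv_c, sr_c=sr_c,
        n_ct_vuln=len(vuln), n_ct_res=len(res),
        n_de_vuln=n_de_vuln, n_de_res=n_de_res,
        provenance={
            "fraction": fraction,
            "vulnerable_types": vuln, "resilient_types": res,
            "vulnerable_contributions": vuln_contrib,
            "resilient_contributions": res_contrib,
        })
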
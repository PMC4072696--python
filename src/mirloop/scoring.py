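"""Fisher's-method loop scoring, consistency and evidence labeling, ranking.

Each Type I/II loop combines the three unadjusted per-node P values with
Fisher's summary statistic T = -2(ln p1 + ln p2 + ln p3); under independent
uniform nulls T is chi-square with 2*3 = 6 degrees of freedom and the loop
score is the upper-tail probability of T.  The score is a ranking device,
not a formal P value: the node tests are not independent in general and
dependence-aware combination is deliberately out of scope.

Consistency compares observed deregulation directions with the edge-sign
structure: species joined by an activating edge should move together,
species joined by a repressing edge should move oppositely.  A loop is
labeled consistent when both the regulator-regulator edge relation and the
miRNA -| mRNA anti-correlation hold; for coherent loops this is equivalent
to all three edges holding simultaneously (for incoherent loops the three
edge relations can never hold at once, so the pairwise rule is the usable
definition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .loops import LOOP_COLUMNS
from .types import SchemaError, sign_of

P_FLOOR = 1e-300
N_NODES = 3
FISHER_DF = 2 * N_NODES

SCORED_COLUMNS = LOOP_COLUMNS + [
    "p1",
    "p2",
    "p3",
    "T",
    "score",
    "dir_mirna",
    "dir_tf",
    "dir_mrna",
    "consistent",
    "evidence_label_tf_edge",
    "evidence_label_mrna_edge",
    "group",
    "rank",
]


@dataclass(frozen=True)
class LoopScore:
    T: float
    score: float
    p1: float
    p2: float
    p3: float


def fisher_score(p1: float, p2: float, p3: float) -> LoopScore:
    """Combine three unadjusted P values into a chi-square(6) tail score."""
    ps = []
    for p in (p1, p2, p3):
        if not (0 < p <= 1):
            raise SchemaError(f"P value {p!r} outside (0, 1]")
        ps.append(max(p, P_FLOOR))
    T = -2.0 * float(np.sum(np.log(ps)))
    score = float(stats.chi2.sf(T, FISHER_DF))
    return LoopScore(T=T, score=score, p1=ps[0], p2=ps[1], p3=ps[2])


def label_consistency(
    loop_type: str,
    tf_mirna_sign: str | None,
    dir_mirna: int,
    dir_tf: int,
    dir_mrna: int,
) -> bool:
    """Pairwise consistency rule for Type I/II loops.

    (a) the regulator-regulator edge relation must hold (miRNA -| TF
    anti-correlation for Type I; TF->miRNA correlation per the edge sign for
    Type II), and (b) the miRNA -| mRNA pair must be anti-correlated.
    """
    for d in (dir_mirna, dir_tf, dir_mrna):
        if d not in (1, -1):
            raise SchemaError("node directions must be +1 or -1; resolve signs first")
    if loop_type == "I":
        edge_ok = dir_mirna == -dir_tf
    elif loop_type == "II":
        if tf_mirna_sign is None or tf_mirna_sign == "":
            raise SchemaError("Type II consistency needs the TF->miRNA sign")
        s2 = sign_of(tf_mirna_sign)
        edge_ok = dir_mirna == s2 * dir_tf
    else:
        raise SchemaError(f"consistency is undefined for loop type {loop_type!r}")
    target_ok = dir_mirna == -dir_mrna
    return bool(edge_ok and target_ok)


def label_evidence(evidence: str) -> str:
    """Map miRNA-target evidence onto the reporting categories.

    predicted & validated -> true_positive; validated only -> false_negative
    (the predictive stage missed a known interaction); predicted only -> novel.
    """
    mapping = {"both": "true_positive", "validated": "false_negative", "predicted": "novel"}
    if evidence not in mapping:
        raise SchemaError(f"unknown evidence token {evidence!r}")
    return mapping[evidence]


def _group_key(row) -> str:
    if row["loop_type"] == "I":
        return f"I-{row['coherence']}"
    if row["loop_type"] == "II":
        return f"II-{row['subtype']}-{row['coherence']}"
    return "III"


GROUPS = [
    "I-coherent",
    "I-incoherent",
    "II-A-coherent",
    "II-A-incoherent",
    "II-B-coherent",
    "II-B-incoherent",
    "III",
]


def annotate_loops(
    loops: pd.DataFrame, mrna_de: pd.DataFrame, mirna_de: pd.DataFrame
) -> pd.DataFrame:
    """Attach Fisher scores, node directions, consistency and evidence labels.

    Node P values are the unadjusted per-transcript values; directions are
    the sign of the moderated t regardless of significance.  Type III loops
    (gene-level) get no score and no consistency flag.
    """
    out = loops.copy()
    n = len(out)
    p1 = np.full(n, np.nan)
    p2 = np.full(n, np.nan)
    p3 = np.full(n, np.nan)
    T = np.full(n, np.nan)
    score = np.full(n, np.nan)
    dir_mirna = np.zeros(n, dtype=int)
    dir_tf = np.zeros(n, dtype=int)
    dir_mrna = np.zeros(n, dtype=int)
    consistent = np.full(n, "", dtype=object)
    ev_tf = np.full(n, "", dtype=object)
    ev_mrna = np.full(n, "", dtype=object)

    for i, (_, row) in enumerate(out.iterrows()):
        if row["evidence_tf_edge"]:
            ev_tf[i] = label_evidence(row["evidence_tf_edge"])
        if row["evidence_mrna_edge"]:
            ev_mrna[i] = label_evidence(row["evidence_mrna_edge"])
        if row["loop_type"] == "III":
            continue
        mirna, tf, mrna = row["mirna"], row["tf_or_gene1"], row["mrna_or_gene2"]
        sc = fisher_score(
            float(mirna_de.loc[mirna, "p"]),
            float(mrna_de.loc[tf, "p"]),
            float(mrna_de.loc[mrna, "p"]),
        )
        p1[i], p2[i], p3[i] = sc.p1, sc.p2, sc.p3
        T[i], score[i] = sc.T, sc.score
        dm = int(mirna_de.loc[mirna, "direction"])
        dt = int(mrna_de.loc[tf, "direction"])
        dg = int(mrna_de.loc[mrna, "direction"])
        dir_mirna[i], dir_tf[i], dir_mrna[i] = dm, dt, dg
        ok = label_consistency(
            row["loop_type"], row["tf_mirna_sign"] or None, dm, dt, dg
        )
        consistent[i] = "consistent" if ok else "inconsistent"

    out["p1"], out["p2"], out["p3"] = p1, p2, p3
    out["T"], out["score"] = T, score
    out["dir_mirna"], out["dir_tf"], out["dir_mrna"] = dir_mirna, dir_tf, dir_mrna
    out["consistent"] = consistent
    out["evidence_label_tf_edge"] = ev_tf
    out["evidence_label_mrna_edge"] = ev_mrna
    return out


def rank_and_group(loops: pd.DataFrame) -> pd.DataFrame:
    """Assign the seven output groups and rank FFLs by ascending score.

    Lower scores mean higher significance.  Ties are broken lexicographically
    on (miRNA, TF, mRNA) for reproducibility.  Type III loops are grouped but
    carry no rank (they involve genes, not specific transcripts).
    """
    out = loops.copy()
    if out.empty:
        out["group"] = pd.Series(dtype=object)
        out["rank"] = pd.Series(dtype=float)
        return out
    out["group"] = out.apply(_group_key, axis=1)
    out["rank"] = np.nan
    for group in out["group"].unique():
        mask = out["group"] == group
        if group == "III":
            continue
        sub = out[mask].sort_values(
            ["score", "mirna", "tf_or_gene1", "mrna_or_gene2"], kind="mergesort"
        )
        out.loc[sub.index, "rank"] = np.arange(1, len(sub) + 1, dtype=float)
    order = {g: i for i, g in enumerate(GROUPS)}
    out = out.sort_values(
        by=["group", "rank", "mirna", "tf_or_gene1", "mrna_or_gene2"],
        key=lambda col: col.map(order) if col.name == "group" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def write_loops(loops: pd.DataFrame, path) -> None:
    loops.to_csv(path, sep="\t", index=False)


def read_loops(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("p1", "p2", "p3", "T", "score", "rank"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("dir_mirna", "dir_tf", "dir_mrna"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(int)
    return df
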
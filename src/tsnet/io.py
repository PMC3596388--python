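"""Readers and writers for the plain-text interchange formats.

Expression travels as a long-format table ``patient<TAB>gene<TAB>time<TAB>value``
(blank or NA value = missing); labels as ``patient<TAB>label`` with labels
+1/-1; networks as a 2-column edge list or SIF (``geneA pp geneB``);
biclusters as one row per bicluster.  All writers round-trip losslessly
through the matching reader.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import Bicluster, ExpressionDataset, GeneStateMatrix, InteractionNetwork, PatientProfile

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_network",
    "write_biclusters",
    "read_biclusters",
    "write_state_matrix",
    "read_state_matrix",
    "write_kernel",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path, labels: dict | None = None) -> ExpressionDataset:
    """Assemble an :class:`ExpressionDataset` from a long-format TSV/CSV.

    Columns (header required): patient, gene, time, value.  A blank or
    NA value, or a (patient, gene, time) triple absent from the file,
    yields a masked (missing) cell.  Duplicated triples and non-numeric
    values are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = ["patient", "gene", "time", "value"][: len(df.columns)]
    if len(df.columns) != 4:
        raise ValueError(f"{path}: expected 4 columns (patient, gene, time, value)")
    df["patient"] = df["patient"].astype(str)
    df["gene"] = df["gene"].astype(str)

    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = df["value"].notna() & vals.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: non-numeric value {df['value'].iloc[row]!r} at data row {row + 1}"
        )
    df["value"] = vals
    df["time"] = df["time"].astype(int)

    dup = df.duplicated(subset=["patient", "gene", "time"], keep=False)
    if dup.any():
        p, g, t = df.loc[dup, ["patient", "gene", "time"]].iloc[0]
        raise ValueError(f"{path}: duplicated (patient, gene, time) triple ({p}, {g}, {t})")

    patients = list(dict.fromkeys(df["patient"]))
    genes = list(dict.fromkeys(df["gene"]))
    times = sorted(df["time"].unique().tolist())
    p_idx = {p: i for i, p in enumerate(patients)}
    g_idx = {g: i for i, g in enumerate(genes)}
    t_idx = {t: i for i, t in enumerate(times)}

    values = np.full((len(patients), len(genes), len(times)), np.nan)
    mask = np.zeros_like(values, dtype=bool)
    pi = df["patient"].map(p_idx).to_numpy()
    gi = df["gene"].map(g_idx).to_numpy()
    ti = df["time"].map(t_idx).to_numpy()
    present = df["value"].notna().to_numpy()
    values[pi[present], gi[present], ti[present]] = df["value"].to_numpy()[present]
    mask[pi[present], gi[present], ti[present]] = True

    lab = None
    if labels is not None:
        lab = np.array([labels[p] for p in patients], dtype=int)
    ds = ExpressionDataset(patients, genes, times, values, mask, lab)
    ds.validate()
    return ds


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the long-format table; missing cells get an empty value field."""
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["patient", "gene", "time", "value"])
        for i, p in enumerate(dataset.patient_ids):
            for j, g in enumerate(dataset.gene_ids):
                for k, t in enumerate(dataset.time_points):
                    v = repr(float(dataset.values[i, j, k])) if dataset.mask[i, j, k] else ""
                    w.writerow([p, g, t, v])


def read_labels(path: str | Path) -> dict:
    """Read ``patient<TAB>label`` with labels +1 / -1 (header optional)."""
    path = Path(path)
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.strip().split()
            if not parts:
                continue
            if lineno == 1 and parts[-1].lstrip("+-").lower() in ("label", "class"):
                continue
            patient, raw = parts[0], parts[-1]
            try:
                lab = int(raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer label {raw!r}") from exc
            if lab not in (-1, 1):
                raise ValueError(f"{path}:{lineno}: label must be +1 or -1, got {lab}")
            if patient in out:
                raise ValueError(f"{path}:{lineno}: duplicate patient {patient!r}")
            out[patient] = lab
    if not out:
        raise ValueError(f"{path}: empty label file")
    return out


def write_labels(labels: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("patient\tlabel\n")
        for p, lab in labels.items():
            fh.write(f"{p}\t{lab:+d}\n")


def read_network(path: str | Path, gene_universe) -> InteractionNetwork:
    """Read an edge list (2-column TSV) or SIF file, restricted to the universe.

    Edges touching genes outside ``gene_universe``, self-loops and
    duplicates are dropped; counts are logged.
    """
    path = Path(path)
    universe = set(gene_universe)
    raw_edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.strip().split()
            if not parts:
                continue
            if len(parts) == 3:  # SIF: geneA relation geneB
                u, v = parts[0], parts[2]
            elif len(parts) == 2:
                u, v = parts
            else:
                raise ValueError(f"{path}:{lineno}: expected 2 (TSV) or 3 (SIF) fields")
            raw_edges.append((u, v))
    if not raw_edges:
        raise ValueError(f"{path}: empty network file")

    seen, kept = set(), []
    n_self = n_out = n_dup = 0
    for u, v in raw_edges:
        if u == v:
            n_self += 1
            continue
        if u not in universe or v not in universe:
            n_out += 1
            continue
        key = (u, v) if u <= v else (v, u)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        kept.append(key)
    logger.info(
        "network %s: kept %d edges (dropped %d self-loops, %d duplicates, %d outside universe)",
        path.name, len(kept), n_self, n_dup, n_out,
    )
    return InteractionNetwork.from_edges(kept, nodes=sorted(universe))


_BC_COLUMNS = ["patient", "genes", "t_start", "t_end", "profile", "score", "weight"]


def write_biclusters(profiles: list, path: str | Path) -> None:
    """One row per bicluster: patient, genes (;-joined), window, profile, score, weight."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_BC_COLUMNS)
        for prof in profiles:
            weights = prof.weights if prof.weights is not None else [""] * prof.n_biclusters
            for bc, wt in zip(prof.biclusters, weights):
                w.writerow(
                    [
                        prof.patient_id,
                        ";".join(map(str, bc.genes)),
                        bc.t_start,
                        bc.t_end,
                        ";".join(map(str, bc.profile)),
                        repr(float(bc.score)),
                        "" if wt == "" else repr(float(wt)),
                    ]
                )


def read_biclusters(path: str | Path) -> list:
    """Inverse of :func:`write_biclusters`; returns a list of PatientProfile."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != _BC_COLUMNS:
        raise ValueError(f"{path}: unexpected bicluster header {list(df.columns)}")
    profiles: list[PatientProfile] = []
    for patient, grp in df.groupby("patient", sort=False):
        bcs, wts = [], []
        for _, row in grp.iterrows():
            bcs.append(
                Bicluster(
                    genes=tuple(row["genes"].split(";")),
                    t_start=int(row["t_start"]),
                    t_end=int(row["t_end"]),
                    profile=tuple(int(s) for s in row["profile"].split(";")),
                    score=float(row["score"]),
                )
            )
            wts.append(float(row["weight"]) if row["weight"] != "" else np.nan)
        weights = None if np.isnan(wts).all() else np.asarray(wts)
        profiles.append(PatientProfile(patient, bcs, weights))
    return profiles


def write_state_matrix(sm: GeneStateMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene"] + [f"t{t}" for t in sm.time_points])
        for g, row in zip(sm.gene_ids, sm.states):
            w.writerow([g] + [int(s) for s in row])


def read_state_matrix(path: str | Path, Q: int | None = None) -> GeneStateMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    times = [int(c.lstrip("t")) for c in df.columns]
    states = df.to_numpy(dtype=int)
    sm = GeneStateMatrix(list(df.index), times, states, Q or int(states.max()))
    sm.validate()
    return sm


def write_kernel(patient_ids: list, kernel: np.ndarray, path: str | Path) -> None:
    """Patient x patient similarity matrix with id header row and column."""
    df = pd.DataFrame(kernel, index=patient_ids, columns=patient_ids)
    df.to_csv(path, sep="\t", index_label="patient")
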
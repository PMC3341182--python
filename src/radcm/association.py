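"""Frequencies, co-occurrence counts, relative associated density (RAD),
directed link classification and network export.

RAD is a *directional* association measure for binary features: for
features *i* and *j*,

    C(i -> j) = #{cases with both i and j} / #{cases with i} = P(j | i).

Because the pair (C(i -> j), C(j -> i)) is asymmetric it separates
one-way from two-way relationships that a single symmetric score (e.g.
co-occurrence count or correlation) conflates. The same construction
conditioned on a syndrome label, C(syndrome -> symptom) = P(symptom |
syndrome), scores the contribution of each symptom to the syndrome and
drives the RAD feature ranking in :mod:`radcm.selection`.

Orientation convention used throughout: ``C[i][j]`` conditions on the
*row* feature, i.e. counts(i, j) / count(i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import CaseTable

logger = logging.getLogger(__name__)

Block = Literal["symptoms", "syndromes"]


@dataclass
class FrequencyVector:
    """Per-feature appearance counts and probabilities.

    ``p[i] = counts[i] / n_cases`` is the appearance probability of
    feature *i* across all cases.
    """

    names: list[str]
    counts: np.ndarray
    n_cases: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or len(self.names) != self.counts.size:
            raise ValueError("names and counts must align")
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if ((self.counts < 0) | (self.counts > self.n_cases)).any():
            raise ValueError("counts must lie in [0, n_cases]")

    @property
    def p(self) -> np.ndarray:
        return self.counts / self.n_cases

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names, "count": self.counts, "probability": self.p}
        )


@dataclass
class CooccurrenceMatrix:
    """Pairwise simultaneous-occurrence counts.

    ``counts[i][j]`` is the number of cases in which row-feature *i* and
    column-feature *j* are both present. When the row and column
    features are the same set the matrix is symmetric and the diagonal
    holds the marginal counts.
    """

    row_names: list[str]
    col_names: list[str]
    counts: np.ndarray
    n_cases: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_names), len(self.col_names)):
            raise ValueError("counts shape does not match names")

    @property
    def same_set(self) -> bool:
        return self.row_names == self.col_names


@dataclass
class RadMatrix:
    """Directional RAD values; ``C[i][j] = P(column j | row i)``."""

    from_names: list[str]
    to_names: list[str]
    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (len(self.from_names), len(self.to_names)):
            raise ValueError("C shape does not match names")

    @property
    def same_set(self) -> bool:
        return self.from_names == self.to_names

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.C, index=self.from_names, columns=self.to_names)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class Link:
    from_: str
    to: str
    rad_forward: float
    rad_backward: float
    kind: Literal["one_way", "two_way"]


@dataclass
class LinkSet:
    """Classified directed links with the thresholds that produced them."""

    links: list[Link]
    hi: float
    lo: float

    def __iter__(self):
        return iter(self.links)

    def __len__(self) -> int:
        return len(self.links)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "from": l.from_,
                    "to": l.to,
                    "rad_forward": l.rad_forward,
                    "rad_backward": l.rad_backward,
                    "kind": l.kind,
                }
                for l in self.links
            ],
            columns=["from", "to", "rad_forward", "rad_backward", "kind"],
        )


def feature_frequencies(table: CaseTable, which: Block = "symptoms") -> FrequencyVector:
    """Appearance probability of each symptom (or syndrome) across all cases."""
    names, mat = table.block(which)
    if which == "syndromes" and table.n_syndromes == 0:
        logger.info("no syndrome columns; returning empty frequency vector")
    return FrequencyVector(
        names=list(names),
        counts=mat.sum(axis=0, dtype=np.int64),
        n_cases=table.n_cases,
    )


def cooccurrence(
    table: CaseTable, rows: Block = "symptoms", cols: Block = "symptoms"
) -> CooccurrenceMatrix:
    """Count simultaneous occurrences for every (row, column) feature pair."""
    row_names, A = table.block(rows)
    col_names, B = table.block(cols)
    counts = A.T.astype(np.int64) @ B.astype(np.int64)
    return CooccurrenceMatrix(
        row_names=list(row_names),
        col_names=list(col_names),
        counts=counts,
        n_cases=table.n_cases,
    )


def rad(cooc: CooccurrenceMatrix, from_counts: FrequencyVector) -> RadMatrix:
    """Normalise co-occurrence counts by the conditioning (row) margin.

    ``C[i][j] = counts[i][j] / count(i)``. Rows whose conditioning count
    is zero are set to 0 with a warning (the conditional is undefined but
    the matrix stays total). When row and column features are the same
    set, the diagonal is forced to 0: self-association is uninformative.
    """
    if from_counts.names != cooc.row_names:
        raise ValueError(
            "from_counts does not match the co-occurrence row features"
        )
    denom = from_counts.counts.astype(float)
    zero = denom == 0
    if zero.any():
        logger.warning(
            "%d conditioning feature(s) never occur; their RAD rows are 0: %s",
            int(zero.sum()),
            [n for n, z in zip(cooc.row_names, zero) if z],
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(zero[:, None], 0.0, cooc.counts / np.where(zero, 1.0, denom)[:, None])
    if cooc.same_set:
        np.fill_diagonal(C, 0.0)
    return RadMatrix(from_names=list(cooc.row_names), to_names=list(cooc.col_names), C=C)


def symptom_rad(table: CaseTable) -> RadMatrix:
    """Symptom-to-symptom RAD matrix: ``C[i][j] = P(symptom j | symptom i)``."""
    return rad(cooccurrence(table, "symptoms", "symptoms"),
               feature_frequencies(table, "symptoms"))


def syndrome_rad(table: CaseTable) -> RadMatrix:
    """Syndrome-to-syndrome RAD matrix."""
    return rad(cooccurrence(table, "syndromes", "syndromes"),
               feature_frequencies(table, "syndromes"))


def syndrome_symptom_rad(table: CaseTable) -> RadMatrix:
    """Contribution of each symptom to each syndrome.

    ``C[k][s] = P(symptom s | syndrome k)`` — rows condition on the
    syndrome, so each row profiles the symptom pattern of one syndrome.
    """
    return rad(cooccurrence(table, "syndromes", "symptoms"),
               feature_frequencies(table, "syndromes"))


def classify_links(radm: RadMatrix, hi: float = 0.5, lo: float = 0.1) -> LinkSet:
    """Classify directed feature pairs into one-way and two-way links.

    For each unordered pair {i, j} with forward value ``f = C[i][j]`` and
    backward value ``b = C[j][i]``:

    * ``one_way``  i -> j when ``f >= hi`` and ``b <= lo``;
    * ``two_way``  when both directions are ``>= hi`` (recorded once,
      oriented so that ``rad_forward >= rad_backward``);
    * excluded otherwise.

    Links are sorted by ``rad_forward`` descending, ties broken by
    (from, to) name order.
    """
    if not radm.same_set:
        raise ValueError("classify_links needs a same-set (square) RAD matrix")
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"need 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    names = radm.from_names
    C = radm.C
    links: list[Link] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            f, b = float(C[i, j]), float(C[j, i])
            if f >= hi and b >= hi:
                if (b, names[j]) > (f, names[i]):
                    links.append(Link(names[j], names[i], b, f, "two_way"))
                else:
                    links.append(Link(names[i], names[j], f, b, "two_way"))
            elif f >= hi and b <= lo:
                links.append(Link(names[i], names[j], f, b, "one_way"))
            elif b >= hi and f <= lo:
                links.append(Link(names[j], names[i], b, f, "one_way"))
    links.sort(key=lambda l: (-l.rad_forward, l.from_, l.to))
    return LinkSet(links=links, hi=hi, lo=lo)


def export_network(
    links: LinkSet,
    freqs: FrequencyVector,
    path: str | Path,
    format: Literal["edge_list", "graphml"] = "edge_list",
) -> None:
    """Write the link network as a TSV edge list or GraphML.

    Every link endpoint must have an entry in ``freqs``; node frequency
    is attached as a node attribute in GraphML output.
    """
    known = set(freqs.names)
    for l in links:
        for end in (l.from_, l.to):
            if end not in known:
                raise ValueError(f"link endpoint {end!r} has no frequency entry")
    path = Path(path)
    if format == "edge_list":
        links.to_frame().to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        g = nx.DiGraph()
        p = dict(zip(freqs.names, freqs.p))
        for l in links:
            for end in (l.from_, l.to):
                if end not in g:
                    g.add_node(end, frequency=float(p[end]))
            g.add_edge(
                l.from_,
                l.to,
                rad_forward=float(l.rad_forward),
                rad_backward=float(l.rad_backward),
                kind=l.kind,
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {format!r}")
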
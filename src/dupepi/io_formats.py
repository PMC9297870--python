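"""Readers and writers for every external representation of the pipeline.

Delimited panel/fragment/metadata tables, GENEPOP and STRUCTURE exports
of the genotype matrix, and Newick trees.  All readers validate closed
vocabularies and raise instead of silently coercing; every writer has a
matching reader that round-trips on values.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .trees import TreeNode

logger = logging.getLogger("dupepi")

#: Closed marker vocabulary of the qPCR panel.
MARKERS = ("EPSPS", "TypeI", "TypeII", "MGE", "ALS")

#: The three geographical regions used throughout.
REGIONS = ("Central Great Plains", "Northern Plains", "Pacific Northwest")

#: Ct strings interpreted as "no amplification" by default.
DEFAULT_NO_AMP_TOKENS = frozenset({"", "NA", "Undetermined"})

#: Sizing-ladder range (bp) enforced on fragment sizes.
LADDER_RANGE = (35.0, 500.0)

NO_AMP = math.nan  # sentinel Ct for non-amplifying reactions


def is_no_amp(ct: float) -> bool:
    return isinstance(ct, float) and math.isnan(ct)


# ----------------------------------------------------------------------
# domain tables
# ----------------------------------------------------------------------
@dataclass
class PanelTable:
    """qPCR Ct table: individual, population, marker, ct, replicate.

    ``ct`` is NaN for no-amplification reactions.  Every
    (individual, replicate) block must contain an ALS (reference) row.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["individual", "population", "marker", "ct", "replicate"]
        missing_cols = [c for c in required if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"panel table missing columns {missing_cols}")
        bad = ~self.df["marker"].isin(MARKERS)
        if bad.any():
            row = self.df.index[bad][0]
            raise ValueError(
                f"unknown marker {self.df.loc[row, 'marker']!r} in row {row}"
            )
        finite = self.df["ct"].dropna()
        if (finite < 0).any() or np.isinf(finite).any():
            raise ValueError("Ct values must be finite and non-negative or NO_AMP")
        has_als = (
            self.df.assign(is_als=self.df["marker"] == "ALS")
            .groupby(["individual", "replicate"])["is_als"]
            .any()
        )
        if not has_als.all():
            culprits = sorted({i for i, _ in has_als.index[~has_als]})
            raise ValueError(f"individuals lacking an ALS row: {culprits}")

    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in self.df["individual"]:
            seen.setdefault(i)
        return list(seen)


@dataclass
class FragmentTable:
    """SSR fragment sizes: individual, population, locus, size1, size2 (bp)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["individual", "population", "locus", "size1", "size2"]
        missing_cols = [c for c in required if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"fragment table missing columns {missing_cols}")
        lo, hi = LADDER_RANGE
        for col in ("size1", "size2"):
            vals = self.df[col].dropna()
            if ((vals < lo) | (vals > hi)).any():
                raise ValueError(f"{col} outside sizing-ladder range {LADDER_RANGE}")
        # normalize size1 <= size2 where both present
        s1, s2 = self.df["size1"].to_numpy(float), self.df["size2"].to_numpy(float)
        swap = np.zeros(len(s1), dtype=bool)
        both = ~np.isnan(s1) & ~np.isnan(s2)
        swap[both] = s1[both] > s2[both]
        self.df.loc[swap, ["size1", "size2"]] = self.df.loc[swap, ["size2", "size1"]].to_numpy()


@dataclass
class PopulationMetadata:
    """Population -> region (and optional coordinates / resistance status)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["population", "region"]
        missing_cols = [c for c in required if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"metadata missing columns {missing_cols}")
        bad = ~self.df["region"].isin(REGIONS)
        if bad.any():
            raise ValueError(
                f"unknown region(s): {sorted(self.df.loc[bad, 'region'].unique())}"
            )
        if self.df["population"].duplicated().any():
            raise ValueError("duplicate population rows in metadata")
        self._region = dict(zip(self.df["population"], self.df["region"]))

    def region_of(self, population: str) -> str:
        try:
            return self._region[population]
        except KeyError:
            raise KeyError(f"population {population!r} absent from metadata") from None

    def __contains__(self, population: str) -> bool:
        return population in self._region


# ----------------------------------------------------------------------
# delimited tables
# ----------------------------------------------------------------------
def _sniff_delimiter(path: str, declared: str | None) -> str:
    if declared is not None:
        return declared
    with open(path) as fh:
        header = fh.readline()
    # auto-detection deliberately limited to comma/tab
    return "\t" if header.count("\t") > header.count(",") else ","


def read_panel_table(
    path: str,
    delimiter: str | None = None,
    no_amp_tokens: frozenset[str] = DEFAULT_NO_AMP_TOKENS,
) -> PanelTable:
    """Read a delimited Ct table; NO_AMP tokens become the NaN sentinel."""
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype={"individual": str, "population": str}, keep_default_na=False)
    if "replicate" not in df.columns:
        df["replicate"] = 1
    raw = df["ct"].astype(str).str.strip()
    is_sentinel = raw.isin(no_amp_tokens)
    ct = pd.to_numeric(raw.where(~is_sentinel, other="nan"), errors="coerce")
    unparsed = ct.isna() & ~is_sentinel
    if unparsed.any():
        line = int(df.index[unparsed][0]) + 2  # header is line 1
        raise ValueError(f"unparseable Ct value {raw[unparsed].iloc[0]!r} at line {line}")
    df["ct"] = ct
    df["replicate"] = df["replicate"].astype(int)
    try:
        return PanelTable(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_panel_table(panel: PanelTable, path: str, delimiter: str = ",") -> None:
    out = panel.df.copy()
    out["ct"] = out["ct"].map(lambda v: "NA" if math.isnan(v) else repr(float(v)))
    out.to_csv(path, sep=delimiter, index=False)


def read_fragment_table(path: str, delimiter: str | None = None) -> FragmentTable:
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype={"individual": str, "population": str, "locus": str})
    df["size1"] = pd.to_numeric(df["size1"], errors="coerce")
    df["size2"] = pd.to_numeric(df["size2"], errors="coerce")
    return FragmentTable(df)


def write_fragment_table(frag: FragmentTable, path: str, delimiter: str = ",") -> None:
    frag.df.to_csv(path, sep=delimiter, index=False)


def read_metadata(path: str, delimiter: str | None = None) -> PopulationMetadata:
    sep = _sniff_delimiter(path, delimiter)
    return PopulationMetadata(pd.read_csv(path, sep=sep, dtype={"population": str}))


def write_metadata(meta: PopulationMetadata, path: str, delimiter: str = ",") -> None:
    meta.df.to_csv(path, sep=delimiter, index=False)


# ----------------------------------------------------------------------
# genotype matrix (long delimited form used by the CLI)
# ----------------------------------------------------------------------
def write_genotype_matrix(gm: GenotypeMatrix, path: str, delimiter: str = ",") -> None:
    rows = []
    for i, (ind, pop) in enumerate(zip(gm.individuals, gm.populations)):
        for j, locus in enumerate(gm.loci):
            a, b = gm.data[i, j]
            rows.append(
                (ind, pop, locus,
                 "" if a == MISSING else int(a),
                 "" if b == MISSING else int(b))
            )
    pd.DataFrame(rows, columns=["individual", "population", "locus", "allele1", "allele2"]).to_csv(
        path, sep=delimiter, index=False
    )


def read_genotype_matrix(path: str, delimiter: str | None = None) -> GenotypeMatrix:
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype={"individual": str, "population": str, "locus": str})
    individuals: list[str] = []
    populations: list[str] = []
    for ind, pop in zip(df["individual"], df["population"]):
        if ind not in individuals:
            individuals.append(ind)
            populations.append(pop)
    loci = list(dict.fromkeys(df["locus"]))
    data = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int64)
    ind_ix = {v: k for k, v in enumerate(individuals)}
    loc_ix = {v: k for k, v in enumerate(loci)}
    for _, row in df.iterrows():
        i, j = ind_ix[row["individual"]], loc_ix[row["locus"]]
        a1 = MISSING if pd.isna(row["allele1"]) else int(row["allele1"])
        a2 = MISSING if pd.isna(row["allele2"]) else int(row["allele2"])
        data[i, j] = (a1, a2)
    return GenotypeMatrix(individuals, populations, loci, data)


# ----------------------------------------------------------------------
# GENEPOP
# ----------------------------------------------------------------------
def write_genepop(gm: GenotypeMatrix, path: str, title: str = "dupepi export") -> None:
    """Write the matrix in GENEPOP format (3-digit alleles, 000 missing)."""
    labels = gm.data[gm.data != MISSING]
    if labels.size and (labels.min() < 1 or labels.max() > 999):
        raise ValueError("allele labels must lie in 1..999 for 3-digit GENEPOP encoding")
    for j, locus in enumerate(gm.loci):
        col = gm.data[:, j, :]
        if np.unique(col[col != MISSING]).size > 999:
            raise ValueError(f"locus {locus}: more than 999 distinct alleles")
    lines = [title]
    lines.extend(gm.loci)
    for pop in gm.population_ids():
        lines.append("Pop")
        for i in gm.population_index(pop):
            cell_tokens = []
            for j in range(gm.n_loci):
                a, b = gm.data[i, j]
                if a == MISSING:
                    cell_tokens.append("000000")
                else:
                    cell_tokens.append(f"{a:03d}{b:03d}")
            lines.append(f"{gm.individuals[i]} ,  " + " ".join(cell_tokens))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genepop(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        # locus names may be one per line or comma-separated
        loci.extend(tok.strip() for tok in lines[i].split(",") if tok.strip())
        i += 1
    individuals: list[str] = []
    populations: list[str] = []
    cells: list[list[tuple[int, int]]] = []
    pop_counter = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_counter += 1
            i += 1
            continue
        name, _, geno = lines[i].partition(",")
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ValueError(f"{path}: sample line with {len(tokens)} genotypes, expected {len(loci)}")
        row = []
        for tok in tokens:
            a, b = int(tok[:3]), int(tok[3:])
            row.append((MISSING, MISSING) if a == 0 or b == 0 else (a, b))
        individuals.append(name.strip())
        populations.append(f"pop{pop_counter}")
        cells.append(row)
        i += 1
    data = np.array(cells, dtype=np.int64) if cells else np.empty((0, len(loci), 2), np.int64)
    return GenotypeMatrix(individuals, populations, loci, data)


# ----------------------------------------------------------------------
# STRUCTURE (one allele per row, -9 missing)
# ----------------------------------------------------------------------
STRUCTURE_MISSING = -9


def write_structure_input(gm: GenotypeMatrix, path: str) -> dict[str, dict[int, int]]:
    """Write a two-rows-per-individual STRUCTURE file.

    Alleles are recoded per locus to consecutive positive integers;
    the bijective recode map {locus: {label: code}} is returned so the
    matrix can be reconstructed.
    """
    recode: dict[str, dict[int, int]] = {}
    for j, locus in enumerate(gm.loci):
        col = gm.data[:, j, :]
        labels = np.unique(col[col != MISSING])
        recode[locus] = {int(lab): k + 1 for k, lab in enumerate(labels)}
    pops = gm.population_ids()
    pop_code = {p: k + 1 for k, p in enumerate(pops)}
    with open(path, "w") as fh:
        fh.write("\t".join(["individual", "location"] + list(gm.loci)) + "\n")
        for i, ind in enumerate(gm.individuals):
            for copy in (0, 1):
                codes = []
                for j, locus in enumerate(gm.loci):
                    a = gm.data[i, j, copy]
                    codes.append(
                        STRUCTURE_MISSING if a == MISSING else recode[locus][int(a)]
                    )
                fh.write(
                    "\t".join([ind, str(pop_code[gm.populations[i]])] + [str(c) for c in codes])
                    + "\n"
                )
    return recode


def read_structure_input(
    path: str, recode: dict[str, dict[int, int]] | None = None
) -> GenotypeMatrix:
    """Read a file written by :func:`write_structure_input`.

    With the recode map, original allele labels are restored; without
    it the integer codes themselves become the labels.
    """
    with open(path) as fh:
        header = fh.readline().split("\t")
        loci = [h.strip() for h in header[2:]]
        rows = [ln.split("\t") for ln in fh if ln.strip()]
    if len(rows) % 2:
        raise ValueError("STRUCTURE file must have two rows per individual")
    inverse: dict[str, dict[int, int]] | None = None
    if recode is not None:
        inverse = {loc: {v: k for k, v in m.items()} for loc, m in recode.items()}
    individuals, populations, cells = [], [], []
    for r in range(0, len(rows), 2):
        top, bot = rows[r], rows[r + 1]
        individuals.append(top[0])
        populations.append(f"pop{top[1]}")
        row = []
        for j, locus in enumerate(loci):
            pair = []
            for line in (top, bot):
                code = int(line[2 + j])
                if code == STRUCTURE_MISSING:
                    pair.append(MISSING)
                elif inverse is not None:
                    pair.append(inverse[locus][code])
                else:
                    pair.append(code)
            row.append(tuple(pair))
        cells.append(row)
    return GenotypeMatrix(individuals, populations, loci, np.array(cells, np.int64))


# ----------------------------------------------------------------------
# Newick
# ----------------------------------------------------------------------
def write_newick(tree: TreeNode, path: str | None = None, support_precision: int = 1) -> str:
    """Serialize a tree to Newick with branch lengths and support labels.

    Supports are written for every annotated internal node regardless of
    magnitude (display thresholds are a rendering concern).  Returns the
    Newick string; writes it to ``path`` when given.
    """

    def fmt(node: TreeNode, root: bool) -> str:
        if node.is_leaf:
            core = node.name or ""
        else:
            core = "(" + ",".join(fmt(ch, False) for ch in node.children) + ")"
            if node.support is not None:
                core += f"{node.support:.{support_precision}f}"
            elif node.name:
                core += node.name
        if root:
            return core
        return f"{core}:{node.length:g}"

    text = fmt(tree, True) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


_TOKEN = re.compile(r"\(|\)|,|;|:|[^(),:;]+")


def read_newick(source: str) -> TreeNode:
    """Parse a Newick string (or path to one) written by :func:`write_newick`."""
    text = source
    if "\n" in source or not source.lstrip().startswith("("):
        try:
            with open(source) as fh:
                text = fh.read()
        except OSError:
            text = source
    tokens = _TOKEN.findall(text.strip())
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if tokens[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while tokens[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if tokens[pos] != ")":
                raise ValueError("malformed Newick: expected ')'")
            pos += 1
        if pos < len(tokens) and tokens[pos] not in "(),:;":
            label = tokens[pos]
            pos += 1
            if node.is_leaf:
                node.name = label
            else:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        if pos < len(tokens) and tokens[pos] == ":":
            pos += 1
            node.length = float(tokens[pos])
            pos += 1
        return node

    root = parse_node()
    if tokens[pos] != ";":
        raise ValueError("malformed Newick: missing terminal ';'")
    return root
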
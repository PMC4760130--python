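"""Readers and writers for every external table the tool touches.

Formats
-------
* expression matrix — tab-delimited text; first line holds the sample
  identifiers, the first column the (non-redundant) gene or protein names;
* modules — GMT (one set per line: name, description, gene tokens), extended
  with an optional bracket weight suffix ``GENE[w]`` where ``w`` is a signed
  real; plain tokens parse as unsigned weight +1.0, so the files remain
  loadable by generic GMT parsers;
* sample annotation — tab-delimited, first row feature names, first column
  sample names;
* result tables — module score table, module x sample activity matrix and
  one per-module gene projection table.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ModuleDefinition, ModuleGene, SampleAnnotation
from .exceptions import FormatError

logger = logging.getLogger(__name__)

#: Cell contents treated as missing in the expression table.
DEFAULT_NA_TOKENS = frozenset({"NA", "NaN", ""})

#: Float rendering used for every output table (>= 6 significant digits).
FLOAT_FORMAT = "%.8g"

_WEIGHT_TOKEN = re.compile(r"^(?P<name>.+)\[(?P<weight>[^\[\]]*)\]$")


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path, na_tokens: Iterable[str] = DEFAULT_NA_TOKENS
) -> ExpressionMatrix:
    """Read a tab-delimited genes x samples expression table.

    Cells matching ``na_tokens`` (or empty) are flagged in the missing mask.
    A duplicate gene name, a ragged row or a non-numeric non-NA cell raises
    :class:`FormatError`.
    """
    path = Path(path)
    na = set(na_tokens)
    with path.open("r", encoding="utf-8") as handle:
        lines = handle.read().splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 2:
        raise FormatError(f"{path}: expression table needs a header and at least one gene row")
    header = lines[0].rstrip("\n").split("\t")
    first_row_width = len(lines[1].split("\t"))
    # the header may or may not carry a corner label above the gene column
    sample_ids = header[1:] if len(header) == first_row_width else header
    n_samples = len(sample_ids)

    gene_ids: list[str] = []
    seen: set[str] = set()
    values = np.empty((len(lines) - 1, n_samples), dtype=float)
    mask = np.zeros_like(values, dtype=bool)
    for row, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_samples + 1:
            raise FormatError(
                f"{path}:{row}: expected {n_samples + 1} fields, found {len(fields)}"
            )
        gene = fields[0].strip()
        if gene in seen:
            raise FormatError(f"{path}:{row}: duplicate gene name {gene!r}")
        seen.add(gene)
        gene_ids.append(gene)
        for col, cell in enumerate(fields[1:]):
            token = cell.strip()
            if token in na:
                values[row - 2, col] = np.nan
                mask[row - 2, col] = True
                continue
            try:
                values[row - 2, col] = float(token)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{row}: non-numeric cell {cell!r} for gene {gene!r}"
                ) from exc
    return ExpressionMatrix(values, gene_ids, sample_ids, mask)


def write_expression(X: ExpressionMatrix, path: str | Path, na_token: str = "NA") -> None:
    """Write an expression matrix in the tab-delimited input layout."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as out:
        out.write("GENE\t" + "\t".join(X.sample_ids) + "\n")
        for i, gene in enumerate(X.gene_ids):
            cells = [
                na_token if X.missing_mask[i, j] else FLOAT_FORMAT % X.values[i, j]
                for j in range(X.n_samples)
            ]
            out.write(gene + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# GMT modules
# ---------------------------------------------------------------------------

def _parse_gene_token(token: str, module: str, path: Path, row: int) -> ModuleGene:
    m = _WEIGHT_TOKEN.match(token)
    if m is None:
        return ModuleGene(token, 1.0, sign_defined=False)
    name = m.group("name")
    payload = m.group("weight")
    try:
        weight = float(payload)
    except ValueError as exc:
        raise FormatError(
            f"{path}:{row}: module {module!r}: cannot parse weight {payload!r} "
            f"in token {token!r}"
        ) from exc
    if weight == 0:
        raise FormatError(f"{path}:{row}: module {module!r}: gene {name!r} has zero weight")
    return ModuleGene(name, weight, sign_defined=True)


def read_gmt(path: str | Path) -> list[ModuleDefinition]:
    """Read module definitions from a (weight-extended) GMT file.

    Duplicate gene tokens within one module keep the first occurrence and log
    a warning; a line with fewer than three fields is a format error.
    """
    path = Path(path)
    modules: list[ModuleDefinition] = []
    with path.open("r", encoding="utf-8") as handle:
        for row, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if line.strip() == "":
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{row}: GMT line needs name, description and >=1 gene "
                    f"({len(fields)} fields found)"
                )
            name, description = fields[0], fields[1]
            genes: list[ModuleGene] = []
            seen: set[str] = set()
            for token in fields[2:]:
                token = token.strip()
                if token == "":
                    continue
                gene = _parse_gene_token(token, name, path, row)
                if gene.name in seen:
                    logger.warning(
                        "%s:%d: module %r repeats gene %r; keeping the first occurrence",
                        path, row, name, gene.name,
                    )
                    continue
                seen.add(gene.name)
                genes.append(gene)
            modules.append(ModuleDefinition(name, description, genes))
    return modules


def _format_gene_token(gene: ModuleGene) -> str:
    if not gene.sign_defined:
        return gene.name
    return f"{gene.name}[{FLOAT_FORMAT % gene.weight}]"


def write_gmt(modules: Sequence[ModuleDefinition], path: str | Path) -> None:
    """Serialize modules to the weight-extended GMT dialect."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as out:
        for mod in modules:
            tokens = [_format_gene_token(g) for g in mod.genes]
            out.write("\t".join([mod.name, mod.description, *tokens]) + "\n")


# ---------------------------------------------------------------------------
# sample annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> SampleAnnotation:
    """Read the tab-delimited sample annotation table (samples in rows)."""
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    table.index = table.index.map(str)
    return SampleAnnotation(table)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

SCORE_COLUMNS = [
    "module",
    "size_in_file",
    "size_effective",
    "L1",
    "p_L1",
    "L1_div_L2",
    "p_L1_div_L2",
    "n_outliers",
    "q_L1_BH",
    "q_L1_div_L2_BH",
]

PROJECTION_COLUMNS = ["gene", "weight", "alpha_pc1", "proj_pc2", "is_outlier"]

_SAFE_NAME = re.compile(r"[^A-Za-z0-9._-]+")


def _safe_filename(name: str) -> str:
    return _SAFE_NAME.sub("_", name) or "module"


def write_outputs(
    scores: "Sequence",
    activities: pd.DataFrame,
    projections: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the three result products to ``out_dir``.

    * ``module_scores.tsv`` — one row per retained module (overdispersion L1
      with empirical p-value, coordination L1/L2 with p-value, outlier count,
      plus clearly-labelled Benjamini-Hochberg adjusted columns);
    * ``activities.tsv`` — module x sample activity matrix;
    * ``projections/<module>.tsv`` — per-gene PC1 loading / PC2 projection.

    Returns a mapping of product name to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if len(scores) == 0:
        logger.warning("no retained modules: writing header-only output tables")

    score_table = pd.DataFrame(
        [
            {
                "module": s.module,
                "size_in_file": s.size_in_file,
                "size_effective": s.size_effective,
                "L1": s.L1,
                "p_L1": s.p_L1,
                "L1_div_L2": s.ratio,
                "p_L1_div_L2": s.p_ratio,
                "n_outliers": len(s.outliers),
                "q_L1_BH": s.q_L1,
                "q_L1_div_L2_BH": s.q_ratio,
            }
            for s in scores
        ],
        columns=SCORE_COLUMNS,
    )
    score_path = out_dir / "module_scores.tsv"
    score_table.to_csv(score_path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    written["scores"] = score_path

    act_path = out_dir / "activities.tsv"
    activities.rename_axis("module").to_csv(
        act_path, sep="\t", float_format=FLOAT_FORMAT
    )
    written["activities"] = act_path

    proj_dir = out_dir / "projections"
    proj_dir.mkdir(exist_ok=True)
    for name, table in projections.items():
        missing = [c for c in PROJECTION_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"projection table for {name!r} lacks columns {missing}")
        p = proj_dir / f"{_safe_filename(name)}.tsv"
        table[PROJECTION_COLUMNS].to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
        written[f"projection:{name}"] = p
    return written


def read_activities(path: str | Path) -> pd.DataFrame:
    """Read back a written activity matrix (modules in rows)."""
    return pd.read_csv(path, sep="\t", index_col=0)
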
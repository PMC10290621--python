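"""Mouse knockout ECG/behavior phenotype tables and HR/HRV candidate filtering.

The tables consumed here follow the dialect used in IMPC-derived candidate
summaries: per gene, a free-text cell lists ECG parameters followed by an
up/down arrow that applies to every parameter named since the previous arrow
("HR, RR ↑" means both increased), optionally qualified by a sex in
parentheses ("HR ↑ (M)"). A literal "No" means no ECG phenotype was recorded.
A curated 32-gene candidate table (feedforward central-autonomic-network
expressed genes with ECG knockout phenotypes and GWAS-catalog / MGI
neuropsychiatric annotations) ships with the package; see
:func:`load_candidate_table`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParseError

__all__ = [
    "PARAMETERS",
    "PhenotypeToken",
    "PhenotypeRow",
    "PhenotypeTable",
    "parse_phenotype_string",
    "format_tokens",
    "read_phenotype_table",
    "write_phenotype_table",
    "load_candidate_table",
    "filter_by_phenotype",
    "filter_by_criteria",
    "annotate_npd",
    "LIMITED_ANNOTATION",
]

#: Closed vocabulary of ECG / echocardiography parameters.
PARAMETERS = (
    "HR",
    "HRV",
    "rMSSD",
    "RR",
    "PQ",
    "PR",
    "ST",
    "QTc",
    "QRS",
    "QTc_dispersion",
    "HR_TTE",
    "LVIDd",
    "LVIDs",
)

DIRECTIONS = ("up", "down")
SEXES = ("any", "F", "M")

#: Literal annotation string that marks a gene as lacking NPD evidence.
LIMITED_ANNOTATION = "Limited or no NPD annotations"

_CANONICAL = {p.upper(): p for p in PARAMETERS}
_CANONICAL["QTC DISPERSION"] = "QTc_dispersion"
_CANONICAL["QTC_DISPERSION"] = "QTc_dispersion"

# Longest alternatives first so e.g. HRV wins over HR and HR_TTE over HR.
_TOKEN_RE = re.compile(
    r"""
    (?P<param>QTc[\s_]Dispersion|HR_TTE|rMSSD|LVIDd|LVIDs|HRV|QTc|QRS|HR|RR|PQ|PR|ST)
  | (?P<arrow>[↑↓])
  | \((?P<sex>[FM])\)
  | (?P<sep>[,\s]+)
    """,
    re.VERBOSE | re.IGNORECASE,
)

_ARROW = {"↑": "up", "↓": "down"}
_ARROW_OUT = {"up": "↑", "down": "↓"}


@dataclass(frozen=True, order=True)
class PhenotypeToken:
    """One (parameter, direction, sex) phenotype observation."""

    parameter: str
    direction: str
    sex: str = "any"

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ParseError(f"unknown phenotype parameter {self.parameter!r}")
        if self.direction not in DIRECTIONS:
            raise ParseError(f"invalid direction {self.direction!r}")
        if self.sex not in SEXES:
            raise ParseError(f"invalid sex qualifier {self.sex!r}")


def parse_phenotype_string(raw: str) -> frozenset[PhenotypeToken]:
    """Tokenize one ECG phenotype cell into a set of :class:`PhenotypeToken`.

    Each arrow binds to every parameter named since the previous arrow; a
    ``(F)``/``(M)`` immediately after the arrow restricts those tokens to one
    sex. ``"No"`` (any case) yields the empty set.
    """
    if not raw or not raw.strip():
        raise ParseError("empty phenotype string")
    text = raw.strip()
    if text.lower() in {"no", "none"}:
        return frozenset()

    # Lex the cell into (kind, value) tokens; anything unmatched is an error.
    lexed: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ParseError(
                f"unrecognized phenotype fragment {text[pos:pos + 20]!r} in {raw!r}"
            )
        if m.lastgroup == "param":
            key = re.sub(r"\s+", " ", m.group("param")).upper()
            lexed.append(("param", _CANONICAL[key]))
        elif m.lastgroup == "arrow":
            lexed.append(("arrow", _ARROW[m.group("arrow")]))
        elif m.lastgroup == "sex":
            lexed.append(("sex", m.group("sex").upper()))
        pos = m.end()

    tokens: set[PhenotypeToken] = set()
    pending: list[str] = []
    i = 0
    while i < len(lexed):
        kind, value = lexed[i]
        if kind == "param":
            pending.append(value)
        elif kind == "arrow":
            if not pending:
                raise ParseError(f"arrow with no preceding parameter in {raw!r}")
            sex = "any"
            if i + 1 < len(lexed) and lexed[i + 1][0] == "sex":
                sex = lexed[i + 1][1]
                i += 1
            for p in pending:
                tokens.add(PhenotypeToken(p, value, sex))
            pending = []
        else:  # sex marker not attached to an arrow
            raise ParseError(f"sex qualifier without arrow in {raw!r}")
        i += 1
    if pending:
        raise ParseError(f"parameters {pending!r} missing an arrow in {raw!r}")
    return frozenset(tokens)


def format_tokens(tokens: Iterable[PhenotypeToken]) -> str:
    """Serialize tokens back to the table dialect (round-trips through the parser)."""
    toks = sorted(tokens, key=lambda t: (PARAMETERS.index(t.parameter), t.direction, t.sex))
    if not toks:
        return "No"
    parts = []
    for t in toks:
        name = "QTc Dispersion" if t.parameter == "QTc_dispersion" else t.parameter
        s = f"{name} {_ARROW_OUT[t.direction]}"
        if t.sex != "any":
            s += f" ({t.sex})"
        parts.append(s)
    return ", ".join(parts)


@dataclass
class PhenotypeRow:
    gene_id: str
    ecg_raw: str
    ecg_tokens: frozenset[PhenotypeToken]
    behavior_terms: list[str]
    npd_status: str  # "annotated" | "limited_or_none"
    npd_terms: list[str]


@dataclass
class PhenotypeTable:
    """Per-gene ECG tokens, behavior terms and NPD annotation status."""

    rows: list[PhenotypeRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.rows]
        if len(ids) != len(set(ids)):
            dup = sorted({g for g in ids if ids.count(g) > 1})
            raise ParseError(f"duplicate gene ids in phenotype table: {dup}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.rows]

    def get(self, gene_id: str) -> PhenotypeRow | None:
        for r in self.rows:
            if r.gene_id == gene_id:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.rows],
                "ecg_phenotype": [r.ecg_raw for r in self.rows],
                "behavior_phenotype": [
                    ", ".join(r.behavior_terms) if r.behavior_terms else "No"
                    for r in self.rows
                ],
                "npd_annotation": [
                    LIMITED_ANNOTATION
                    if r.npd_status == "limited_or_none"
                    else ", ".join(r.npd_terms)
                    for r in self.rows
                ],
            }
        )


def _row_from_fields(gene: str, ecg: str, behavior: str, npd: str) -> PhenotypeRow:
    behavior = behavior.strip()
    npd = npd.strip()
    behaviors = [] if behavior.lower() in {"no", "none", ""} else [
        b.strip() for b in behavior.split(",") if b.strip()
    ]
    limited = npd == LIMITED_ANNOTATION
    return PhenotypeRow(
        gene_id=gene.strip(),
        ecg_raw=ecg.strip(),
        ecg_tokens=parse_phenotype_string(ecg),
        behavior_terms=behaviors,
        npd_status="limited_or_none" if limited else "annotated",
        npd_terms=[] if limited else [t.strip() for t in npd.split(",") if t.strip()],
    )


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    """Read a tab-separated phenotype table.

    Expected columns: ``gene_id``, ``ecg_phenotype``, ``behavior_phenotype``,
    ``npd_annotation``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("No")
    required = {"gene_id", "ecg_phenotype", "behavior_phenotype", "npd_annotation"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"phenotype table {path} missing columns: {sorted(missing)}")
    rows = [
        _row_from_fields(
            r["gene_id"], r["ecg_phenotype"], r["behavior_phenotype"], r["npd_annotation"]
        )
        for _, r in df.iterrows()
    ]
    return PhenotypeTable(rows)


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def load_candidate_table() -> PhenotypeTable:
    """Load the packaged 32-gene feedforward-CAN candidate table."""
    ref = resources.files("canprio.data").joinpath("ff_ans_candidates.tsv")
    with resources.as_file(ref) as p:
        return read_phenotype_table(p)


def _token_matches(
    token: PhenotypeToken,
    parameter: str,
    direction: str,
    sex_mode: str,
    hrv_includes_rmssd: bool,
) -> bool:
    params = {parameter}
    if hrv_includes_rmssd and parameter == "HRV":
        # rMSSD is a (vagally mediated) HRV statistic; an HRV criterion
        # matches either parameter.
        params.add("rMSSD")
    if token.parameter not in params or token.direction != direction:
        return False
    if sex_mode == "any":
        return True
    return token.sex in ("any", sex_mode)


def filter_by_phenotype(
    table: PhenotypeTable,
    parameter: str,
    direction: str,
    sex_mode: str = "any",
    hrv_includes_rmssd: bool = True,
) -> list[str]:
    """Genes with at least one token matching ``parameter`` + ``direction``.

    Under ``sex_mode="any"`` sex-specific tokens count (a male-only HR
    increase satisfies an HR-up criterion).
    """
    if parameter not in PARAMETERS:
        raise ParseError(f"unknown phenotype parameter {parameter!r}")
    if direction not in DIRECTIONS:
        raise ParseError(f"invalid direction {direction!r}")
    return [
        r.gene_id
        for r in table.rows
        if any(
            _token_matches(t, parameter, direction, sex_mode, hrv_includes_rmssd)
            for t in r.ecg_tokens
        )
    ]


def filter_by_criteria(
    table: PhenotypeTable,
    criteria: Sequence[tuple[str, str]],
    sex_mode: str = "any",
) -> list[str]:
    """Genes matching any of the (parameter, direction) criteria.

    An empty criterion set selects every gene in the table.
    """
    if not criteria:
        return table.gene_ids
    hits: list[str] = []
    for r in table.rows:
        if any(
            any(_token_matches(t, p, d, sex_mode, True) for t in r.ecg_tokens)
            for p, d in criteria
        ):
            hits.append(r.gene_id)
    return hits


def annotate_npd(
    table: PhenotypeTable, genes: Iterable[str]
) -> dict[str, list[str]]:
    """Partition genes into annotated / limited_or_none / unknown.

    A gene is ``limited_or_none`` iff its annotation cell is the literal
    "Limited or no NPD annotations"; genes absent from the table go to
    ``unknown``.
    """
    out: Mapping[str, list[str]] = {"annotated": [], "limited_or_none": [], "unknown": []}
    for g in genes:
        row = table.get(g)
        if row is None:
            out["unknown"].append(g)
        else:
            out[row.npd_status].append(g)
    return dict(out)
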
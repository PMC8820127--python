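"""Spectral-tuning and functional-site analysis in bovine RH1 numbering.

Opsin residues are conventionally numbered by homology to the 348-residue
bovine rod opsin (RH1): a query sequence is globally aligned to the bovine
reference (BLOSUM62, affine gaps: open 10, extend 1) and each query
residue inherits the reference position of its aligned column. The module
extracts residues at a curated catalog of spectral-tuning,
chromophore-binding-pocket and kinetic/functional sites, summarizes
per-site variation across species, and compares duplicate gene copies
(percent identity at the amino-acid and nucleotide level, indel positions
in reference numbering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .errors import ValidationError
from .io_formats import read_fasta_string

GAP_MARK = "-"
MISSING_MARK = "?"

_MIN_SANE_SCORE = 0.0  # below this the query is flagged as non-homologous


def load_reference() -> tuple[str, str]:
    """(name, sequence) of the packaged bovine rhodopsin reference."""
    text = resources.files("opsinsel.data").joinpath("bovine_rh1.fasta").read_text()
    [(name, seq)] = read_fasta_string(text)
    return name, seq


@dataclass(frozen=True)
class ReferenceNumbering:
    """Mapping of 1-based query residue indices to reference positions.

    ``mapping`` omits query residues that align to reference gaps. The map
    is strictly increasing and no reference position appears twice.
    ``trusted`` is False when the alignment score fell below the sanity
    floor (the query does not look homologous to the reference).
    """

    query_name: str
    mapping: dict[int, int]
    alignment_score: float
    trusted: bool = True

    def reference_to_query(self) -> dict[int, int]:
        return {ref: q for q, ref in self.mapping.items()}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def map_to_reference_numbering(
    query: str,
    reference: str | None = None,
    query_name: str = "query",
) -> ReferenceNumbering:
    """Number a query protein by global alignment to the reference.

    The reference defaults to the packaged bovine rhodopsin. Ties in the
    alignment are broken deterministically (the aligner's first optimal
    alignment, which prefers matches over opening gaps).
    """
    if not query:
        raise ValidationError("empty query sequence")
    if reference is None:
        _, reference = load_reference()
    aligner = _make_aligner()
    alignment = aligner.align(reference.upper(), query.upper())[0]
    mapping: dict[int, int] = {}
    ref_blocks, query_blocks = alignment.aligned
    for (r0, r1), (q0, q1) in zip(ref_blocks, query_blocks):
        for offset in range(r1 - r0):
            mapping[q0 + offset + 1] = r0 + offset + 1
    return ReferenceNumbering(
        query_name=query_name,
        mapping=mapping,
        alignment_score=float(alignment.score),
        trusted=float(alignment.score) >= _MIN_SANE_SCORE,
    )


# ---------------------------------------------------------------------------
# Site catalog


@dataclass(frozen=True)
class SiteCatalog:
    """Curated opsin sites in bovine RH1 numbering.

    Categories: ``spectral-tuning`` (sites whose substitution shifts the
    pigment's wavelength of maximal absorbance), ``chromophore-pocket``
    (residues lining the retinal-binding cavity) and ``kinetic/functional``
    (sites affecting activation/retinal-release kinetics).
    """

    entries: pd.DataFrame = field(repr=False)

    def positions(self, category: str | None = None) -> list[int]:
        df = self.entries
        if category is not None:
            df = df[df["category"] == category]
        return sorted(df["position"].unique().tolist())

    def annotation(self, position: int) -> pd.DataFrame:
        return self.entries[self.entries["position"] == position]


def load_default_catalog() -> SiteCatalog:
    text = resources.files("opsinsel.data").joinpath("site_catalog.tsv").read_text()
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t", keep_default_na=False)
    df["position"] = df["position"].astype(int)
    dupes = df.duplicated(subset=["position", "category"])
    if dupes.any():
        raise ValidationError("catalog has duplicate (position, category) rows")
    return SiteCatalog(entries=df)


# ---------------------------------------------------------------------------
# Residue extraction


def extract_site_residues(
    seqs: list[tuple[str, str]],
    catalog: SiteCatalog | None = None,
    reference: str | None = None,
    positions: list[int] | None = None,
) -> pd.DataFrame:
    """Residues of each species at every catalog position.

    Returns a species x position DataFrame of residue letters, with ``-``
    where the site falls in an alignment gap of the query and ``?`` for a
    sequence that could not be mapped (flagged untrusted).
    """
    if catalog is None and positions is None:
        catalog = load_default_catalog()
    if positions is None:
        positions = catalog.positions()
    if reference is None:
        _, reference = load_reference()
    rows = {}
    for name, seq in seqs:
        numbering = map_to_reference_numbering(seq, reference, query_name=name)
        if not numbering.trusted:
            rows[name] = {pos: MISSING_MARK for pos in positions}
            continue
        inverse = numbering.reference_to_query()
        row = {}
        for pos in positions:
            q = inverse.get(pos)
            row[pos] = seq[q - 1].upper() if q is not None else GAP_MARK
        rows[name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")[positions]
    table.index.name = "species"
    table.columns.name = "position"
    return table


def substitution_calls(table: pd.DataFrame, reference: str | None = None) -> pd.DataFrame:
    """Render residues as substitution calls against the reference (e.g. D83N).

    Residues equal to the reference, gaps and missing entries are left as-is.
    """
    if reference is None:
        _, reference = load_reference()
    out = table.copy()
    for pos in table.columns:
        ref_res = reference[pos - 1]
        out[pos] = [
            f"{ref_res}{pos}{res}" if res not in (ref_res, GAP_MARK, MISSING_MARK) else res
            for res in table[pos]
        ]
    return out


def variation_report(
    table: pd.DataFrame, catalog: SiteCatalog | None = None
) -> pd.DataFrame:
    """Per-site summary of observed residues across species.

    Residues are joined with ``/`` in descending frequency (ties broken
    alphabetically); a site is flagged variable when more than one residue
    occurs. Sites observed only as gaps/missing are omitted.
    """
    if table.empty:
        raise ValidationError("empty residue table")
    records = []
    for pos in table.columns:
        residues = [r for r in table[pos] if r not in (GAP_MARK, MISSING_MARK)]
        if not residues:
            continue
        counts = pd.Series(residues).value_counts()
        ordered = sorted(counts.index, key=lambda r: (-counts[r], r))
        rec = {
            "position": int(pos),
            "residues": "/".join(ordered),
            "variable": len(ordered) > 1,
            "n_species": len(residues),
        }
        if catalog is not None:
            ann = catalog.annotation(int(pos))
            rec["known_from"] = "; ".join(ann["known_from"].unique())
            rec["known_variants"] = "; ".join(v for v in ann["known_variants"].unique() if v)
        records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Duplicate-copy comparison


@dataclass(frozen=True)
class CopyComparison:
    """Identity report for two coding-sequence copies of a gene."""

    aa_identity_pct: float
    nt_identity_pct: float
    n_aa_differences: int
    indels: list[dict]
    aligned_aa_columns: int

    def as_dict(self) -> dict:
        return {
            "aa_identity_pct": self.aa_identity_pct,
            "nt_identity_pct": self.nt_identity_pct,
            "n_aa_differences": self.n_aa_differences,
            "indels": self.indels,
            "aligned_aa_columns": self.aligned_aa_columns,
        }


def _translate_cds(seq: str, label: str) -> str:
    if len(seq) % 3 != 0:
        raise ValidationError(f"{label}: length not a multiple of 3")
    protein = str(Seq(seq).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValidationError(f"{label}: internal stop codon in translation")
    return protein


def pairwise_copy_comparison(
    copy1: str, copy2: str, reference: str | None = None
) -> CopyComparison:
    """Compare two in-frame coding sequences of duplicate gene copies.

    Translations are globally aligned; percent identity uses aligned
    columns where both sequences are non-gap (so terminal truncations and
    indels do not inflate divergence). The codon alignment is threaded
    through the protein alignment for the nucleotide identity. Indels are
    reported at the reference-numbered position of the residue preceding
    the gap (bovine RH1 numbering by default).
    """
    prot1 = _translate_cds(copy1.upper(), "copy1")
    prot2 = _translate_cds(copy2.upper(), "copy2")
    aligner = _make_aligner()
    alignment = aligner.align(prot1, prot2)[0]
    b1, b2 = alignment.aligned

    aa_match = aa_total = 0
    nt_match = nt_total = 0
    for (s1, e1), (s2, e2) in zip(b1, b2):
        for off in range(e1 - s1):
            a, b = prot1[s1 + off], prot2[s2 + off]
            aa_total += 1
            aa_match += a == b
            c1 = copy1[3 * (s1 + off) : 3 * (s1 + off) + 3].upper()
            c2 = copy2[3 * (s2 + off) : 3 * (s2 + off) + 3].upper()
            for x, y in zip(c1, c2):
                nt_total += 1
                nt_match += x == y
    if aa_total == 0:
        raise ValidationError("no aligned residues between the two copies")

    if reference is None:
        _, reference = load_reference()
    numbering1 = map_to_reference_numbering(prot1, reference, "copy1")

    indels = []
    for i in range(len(b1) - 1):
        skipped1 = b1[i + 1][0] - b1[i][1]  # copy1 residues absent from copy2
        skipped2 = b2[i + 1][0] - b2[i][1]  # copy2 residues absent from copy1
        if skipped1 > 0:
            pos = numbering1.mapping.get(b1[i][1] + 1, b1[i][1] + 1)
            indels.append({"kind": "deletion_in_copy2", "length": skipped1,
                           "reference_position": pos})
        if skipped2 > 0:
            pos = numbering1.mapping.get(b1[i][1], b1[i][1])
            indels.append({"kind": "deletion_in_copy1", "length": skipped2,
                           "reference_position": pos + 1})
    return CopyComparison(
        aa_identity_pct=round(100.0 * aa_match / aa_total, 1),
        nt_identity_pct=round(100.0 * nt_match / nt_total, 1),
        n_aa_differences=aa_total - aa_match,
        indels=indels,
        aligned_aa_columns=aa_total,
    )
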
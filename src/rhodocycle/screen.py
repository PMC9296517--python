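"""Sequence-level screens for rhodopsin-bearing genomes.

Three alignment-based analyses, all driven by packaged single-file
references (no external databases):

* motif extraction at bacteriorhodopsin-homologous positions 85/89/96
  (proton acceptor / stabilizer / proton donor; DTD in BR, DTS in many
  outward pumps of the same clade);
* ATP-synthase c-subunit ion-specificity calls (Na+-binding Q/E/S/T quartet
  vs. lone H+-binding carboxylate), via a user-overridable rule table;
* retinal/β-carotene pathway presence (blh, crtE, crtB, crtI, crtY,
  rhodopsin) by local alignment against exemplar sequences, plus per-sample
  co-occurrence summaries of blh carriers.

Alignments use BLOSUM62 with affine gaps (open 11, extend 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "MotifResult",
    "CSubunitCall",
    "extract_motif",
    "classify_c_subunit",
    "screen_pathway",
    "summarize_cooccurrence",
    "load_reference",
    "load_pathway_exemplars",
    "load_c_subunit_rules",
    "PATHWAY_GENES",
]

PATHWAY_GENES = ["blh", "crtE", "crtB", "crtI", "crtY", "rhodopsin"]

#: BR-homologous positions of the proton-pumping triplet (mature numbering)
MOTIF_POSITIONS = (85, 89, 96)

GAP_OPEN = -11.0
GAP_EXTEND = -1.0
MIN_REFERENCE_COVERAGE = 0.5  # motif mapping
DEFAULT_MIN_IDENTITY = 30.0  # % — pathway presence
DEFAULT_MIN_COVERAGE = 0.5  # of the exemplar — pathway presence


def _data_text(name: str) -> str:
    return resources.files("rhodocycle.data").joinpath(name).read_text()


def load_reference(name: str = "bacteriorhodopsin_mature.fasta") -> tuple[str, str]:
    """(id, sequence) of a packaged single-record FASTA."""
    from io import StringIO

    rec = next(SeqIO.parse(StringIO(_data_text(name)), "fasta"))
    return rec.id, str(rec.seq)


def load_pathway_exemplars(path=None) -> dict[str, tuple[str, str]]:
    """gene -> (exemplar id, sequence).  Default: packaged synthetic exemplars."""
    from io import StringIO

    if path is None:
        handle = StringIO(_data_text("pathway_exemplars_synthetic.fasta"))
    else:
        handle = open(path)
    out = {}
    with handle:
        for rec in SeqIO.parse(handle, "fasta"):
            gene = None
            for token in rec.description.split():
                if token.startswith("gene="):
                    gene = token[5:]
            if gene is None:
                gene = rec.id
            out[gene] = (rec.id, str(rec.seq))
    return out


def load_c_subunit_rules(path=None) -> dict:
    if path is None:
        return yaml.safe_load(_data_text("c_subunit_rules.yaml"))
    with open(path) as fh:
        return yaml.safe_load(fh)


def _aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    aligner.mode = mode
    if mode == "global":
        # semi-global: terminal gaps are free so N/C-terminal extensions of
        # either sequence do not distort the position mapping
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


@dataclass
class MotifResult:
    query_id: str
    motif: str | None  # e.g. "DTD", "DTS"; None when unmapped
    positions: list[dict]  # per position: br_index, query_index, residue
    alignment_score: float
    coverage: float  # fraction of reference residues aligned
    mapped: bool
    warnings: list[str] = field(default_factory=list)


def extract_motif(
    query: str,
    query_id: str = "query",
    reference: str | None = None,
    positions: tuple[int, ...] = MOTIF_POSITIONS,
) -> MotifResult:
    """Residues of ``query`` at BR-homologous positions.

    Globally aligns the query against the mature-BR reference (semi-global,
    BLOSUM62) and reads off the query residues opposite the requested
    reference positions (1-based).  A gap yields ``-`` with a warning; less
    than 50% reference coverage yields an unmapped result without a motif.
    """
    if reference is None:
        _, reference = load_reference()
    aligner = _aligner("global")
    alignment = aligner.align(reference, query)[0]
    ref_idx, qry_idx = alignment.indices  # -1 marks a gap
    both = (ref_idx >= 0) & (qry_idx >= 0)
    coverage = float(both.sum()) / len(reference)
    if coverage < MIN_REFERENCE_COVERAGE:
        return MotifResult(
            query_id=query_id,
            motif=None,
            positions=[],
            alignment_score=float(alignment.score),
            coverage=coverage,
            mapped=False,
            warnings=[f"alignment covers only {coverage:.0%} of the reference"],
        )
    warn: list[str] = []
    mapped_positions: list[dict] = []
    motif_chars = []
    for pos in positions:
        cols = np.flatnonzero(ref_idx == pos - 1)
        if cols.size == 0 or qry_idx[cols[0]] < 0:
            motif_chars.append("-")
            mapped_positions.append(
                {"br_index": pos, "query_index": None, "residue": "-"}
            )
            warn.append(f"gap opposite reference position {pos}")
            continue
        qi = int(qry_idx[cols[0]])
        motif_chars.append(query[qi])
        mapped_positions.append(
            {"br_index": pos, "query_index": qi + 1, "residue": query[qi]}
        )
    if warn:
        warnings.warn(f"{query_id}: " + "; ".join(warn))
    return MotifResult(
        query_id=query_id,
        motif="".join(motif_chars),
        positions=mapped_positions,
        alignment_score=float(alignment.score),
        coverage=coverage,
        mapped=True,
        warnings=warn,
    )


@dataclass
class CSubunitCall:
    query_id: str
    call: str  # H_plus | Na_plus | unclassified
    matched_residues: dict  # rule position -> aligned query residue ('-' for gap)
    reason: str = ""


def classify_c_subunit(
    query: str,
    query_id: str = "query",
    rule_table: dict | None = None,
    reference: str | None = None,
) -> CSubunitCall:
    """Ion-specificity call for an ATP-synthase c subunit.

    ``Na_plus`` iff every Na+-quartet position (aligned to the packaged
    reference) carries an accepted residue; otherwise ``H_plus`` iff the
    binding-site carboxylate position holds E/D; otherwise ``unclassified``.
    A query with no carboxylate anywhere cannot bind either ion this way and
    is unclassified outright.
    """
    rules = load_c_subunit_rules() if rule_table is None else rule_table
    if reference is None:
        _, reference = load_reference("c_subunit_reference_synthetic.fasta")
    if not any(c in query for c in "ED"):
        return CSubunitCall(
            query_id=query_id,
            call="unclassified",
            matched_residues={},
            reason="no carboxylate residue in the sequence",
        )
    aligner = _aligner("global")
    alignment = aligner.align(reference, query)[0]
    ref_idx, qry_idx = alignment.indices

    def residue_at(pos: int) -> str:
        cols = np.flatnonzero(ref_idx == pos - 1)
        if cols.size == 0 or qry_idx[cols[0]] < 0:
            return "-"
        return query[int(qry_idx[cols[0]])]

    quartet = {int(p): str(acc) for p, acc in rules["na_quartet"].items()}
    carbox_pos = int(rules["carboxylate"]["position"])
    carbox_acc = str(rules["carboxylate"]["residues"])
    matched = {pos: residue_at(pos) for pos in sorted(set(quartet) | {carbox_pos})}

    if all(matched[pos] in acc for pos, acc in quartet.items()):
        return CSubunitCall(query_id, "Na_plus", matched,
                            "complete Na+-binding quartet")
    if matched[carbox_pos] in carbox_acc:
        return CSubunitCall(query_id, "H_plus", matched,
                            "binding-site carboxylate without Na+ quartet")
    return CSubunitCall(query_id, "unclassified", matched,
                        "no diagnostic residues at the rule positions")


def _local_best_hit(aligner: PairwiseAligner, exemplar: str, protein: str):
    """(identity %, exemplar coverage) of the best local alignment."""
    alignments = aligner.align(exemplar, protein)
    if len(alignments) == 0:
        return 0.0, 0.0
    alignment = alignments[0]
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    if aligned_cols == 0:
        return 0.0, 0.0
    identity = 100.0 * counts.identities / aligned_cols
    ref_idx = alignment.indices[0]
    covered = int(((ref_idx >= 0) & (alignment.indices[1] >= 0)).sum())
    return identity, covered / len(exemplar)


def screen_pathway(
    proteome: dict[str, str],
    references: dict[str, tuple[str, str]] | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    genome_id: str = "genome",
    taxon: str = "",
    sample: str = "",
) -> dict:
    """One pathway-presence row for a proteome.

    Every protein is locally aligned against every gene-family exemplar; a
    gene is present when its best hit reaches ``min_identity`` percent
    identity over at least ``min_coverage`` of the exemplar length.
    """
    refs = load_pathway_exemplars() if references is None else references
    if not proteome:
        warnings.warn(f"{genome_id}: empty proteome; reporting all genes absent")
    aligner = _aligner("local")
    row: dict = {"genome_id": genome_id, "taxon": taxon, "sample": sample}
    for gene in PATHWAY_GENES:
        if gene not in refs:
            raise ValueError(f"no exemplar provided for gene {gene!r}")
        ex_id, ex_seq = refs[gene]
        best_identity, best_cov, best_hit = 0.0, 0.0, ""
        for pid, pseq in proteome.items():
            if not pseq:
                continue
            identity, cov = _local_best_hit(aligner, ex_seq, pseq)
            if cov >= min_coverage and identity > best_identity:
                best_identity, best_cov, best_hit = identity, cov, pid
        row[f"{gene}_present"] = bool(
            best_identity >= min_identity and best_cov >= min_coverage
        )
        row[f"{gene}_identity_pct"] = round(best_identity, 4)
        row[f"{gene}_best_hit"] = best_hit
    return row


def screen_table(rows: list[dict]) -> pd.DataFrame:
    """Stack presence rows into the tabular ScreenResult form."""
    return pd.DataFrame(rows)


def summarize_cooccurrence(table: pd.DataFrame,
                           focal_taxon: str = "Actinobacteria") -> dict:
    """Per-sample blh carrier summary.

    For each sample: number of blh-positive rows and the fraction of those
    rows affiliated with ``focal_taxon`` (NA when the sample has no blh
    carriers); overall, the fraction of samples with at least one carrier.
    """
    if "sample" not in table or "blh_present" not in table:
        raise ValueError("table needs 'sample' and 'blh_present' columns")
    per_sample = []
    for sample, grp in table.groupby("sample", sort=True):
        pos = grp[grp["blh_present"].astype(bool)]
        n_pos = int(len(pos))
        frac = (
            float((pos["taxon"] == focal_taxon).mean()) if n_pos else float("nan")
        )
        per_sample.append(
            {
                "sample": sample,
                "blh_positive": n_pos,
                f"{focal_taxon.lower()}_fraction": frac,
            }
        )
    n_samples = len(per_sample)
    n_with = sum(1 for r in per_sample if r["blh_positive"] > 0)
    return {
        "per_sample": per_sample,
        "n_samples": n_samples,
        "n_samples_with_blh": n_with,
        "overall_blh_sample_fraction_pct": 100.0 * n_with / n_samples
        if n_samples
        else float("nan"),
    }
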
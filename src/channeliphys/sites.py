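"""Map iGluR sequences onto mature GluA2 numbering and classify ligand specificity.

The workflow is: globally align a query protein against the mature rat GluA2
reference (:func:`map_to_reference`), read off the residues at the
deterministic ligand-binding-domain and pore positions
(:func:`extract_sites`), and apply the residue rules for glutamate versus
glycine/D-serine specificity (:func:`predict_ligand`):

* glutamate:        653 in {G, S, T}  and  655 == T  and  732 == Y
* glycine/D-serine: 653 == S  and  655 in {V, L, A, I, P}  and  732 == F

Profiles satisfying neither rule are "unpredictable". Missing backbone
contacts (no D at 705, no R at 485) are reported as warnings but never
change the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .reference import (
    BACKBONE_CONTACT_POSITIONS,
    SIDECHAIN_CONTACT_POSITIONS,
    QRN_POSITION,
    PLUS4_POSITION,
    M3_MOTIF_START,
    LURCHER_POSITION,
    SITE_G_POSITIONS,
    glua2_reference,
)

GAP = "-"
UNMAPPED = "unmapped"

GLUTAMATE_653 = set("GST")
GLUTAMATE_655 = {"T"}
GLUTAMATE_732 = {"Y"}
GLYCINE_653 = {"S"}
GLYCINE_655 = set("VLAIP")
GLYCINE_732 = {"F"}

# Reference span containing every annotated site; coverage is judged here.
_SITE_SPAN = (440, 740)


@dataclass
class ReferenceMap:
    """Monotone 1-based mapping reference_position -> query_index.

    Reference positions aligned to a gap in the query are absent from
    ``mapping``; positions outside the aligned span are "unmapped".
    """

    query_id: str
    mapping: dict[int, int]
    score: float
    coverage: float
    aligned_ref_span: tuple[int, int]

    def query_index(self, ref_pos: int) -> int | None:
        return self.mapping.get(ref_pos)

    def status(self, ref_pos: int) -> str:
        """One of 'mapped', 'gap' (deletion inside span), 'unmapped'."""
        if ref_pos in self.mapping:
            return "mapped"
        lo, hi = self.aligned_ref_span
        return "gap" if lo <= ref_pos <= hi else UNMAPPED


@dataclass
class SiteProfile:
    """Residues observed at the deterministic GluA2-numbered positions."""

    query_id: str
    backbone: dict[int, str]
    sidechain: dict[int, str]
    qrn: str
    plus4: str
    m3_motif: str
    lurcher: str
    siteG: str
    warnings: list[str] = field(default_factory=list)

    def residue(self, pos: int) -> str:
        if pos in self.backbone:
            return self.backbone[pos]
        return self.sidechain[pos]


@dataclass
class LigandPrediction:
    label: str  # glutamate | glycine/D-serine | unpredictable
    warnings: list[str] = field(default_factory=list)


def _default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # free end gaps so fragments are not penalized for partial span
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.86
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def map_to_reference(
    query_seq: str,
    reference_seq: str | None = None,
    query_id: str = "query",
    min_coverage: float = 0.3,
    signal_peptide_offset: int = 0,
) -> ReferenceMap:
    """Globally align ``query_seq`` to the reference and build a position map.

    Parameters
    ----------
    query_seq : str
        Protein sequence (standard alphabet; X tolerated), >= 50 residues.
    reference_seq : str, optional
        Mature-numbered reference; defaults to the bundled synthetic GluA2
        stand-in. Pass the real mature P19491 sequence when available.
    min_coverage : float
        Minimum fraction of the 440-740 site span that must align;
        below this an "unreliable mapping" error is raised.
    signal_peptide_offset : int
        Number of leading precursor residues to strip from the reference
        before mature numbering (0 for an already-mature sequence).
    """
    reference_seq = (reference_seq or glua2_reference())[signal_peptide_offset:]
    query_seq = str(query_seq).upper().replace("*", "")
    if len(query_seq) < 50 or len(reference_seq) < 50:
        raise ValueError("sequences must be at least 50 residues long")
    bad = set(query_seq) - set("ACDEFGHIKLMNPQRSTVWYXBZ")
    if bad:
        raise ValueError(f"non-amino-acid characters in query: {sorted(bad)}")

    aligner = _default_aligner()
    alignment = aligner.align(reference_seq, query_seq)[0]
    ref_blocks, query_blocks = alignment.aligned
    mapping: dict[int, int] = {}
    for (rs, re), (qs, qe) in zip(ref_blocks, query_blocks):
        for offset in range(re - rs):
            mapping[rs + offset + 1] = qs + offset + 1  # 1-based

    if not mapping:
        raise ValueError("unreliable mapping: no aligned residues")
    span = (min(mapping), max(mapping))
    lo, hi = _SITE_SPAN
    span_positions = [p for p in range(lo, hi + 1) if p in mapping]
    coverage = len(span_positions) / (hi - lo + 1)
    if coverage < min_coverage:
        raise ValueError(
            f"unreliable mapping: coverage {coverage:.2f} over the LBD span "
            f"{_SITE_SPAN} is below {min_coverage}"
        )
    return ReferenceMap(
        query_id=query_id,
        mapping=mapping,
        score=float(alignment.score),
        coverage=coverage,
        aligned_ref_span=span,
    )


def _read_site(refmap: ReferenceMap, query_seq: str, pos: int, warnings: list[str]) -> str:
    status = refmap.status(pos)
    if status == "mapped":
        return query_seq[refmap.mapping[pos] - 1]
    warnings.append(f"{'gap' if status == 'gap' else 'unmapped'}_at_site_{pos}")
    return GAP if status == "gap" else UNMAPPED


def extract_sites(refmap: ReferenceMap, query_seq: str) -> SiteProfile:
    """Read the query residues at every deterministic GluA2-numbered site.

    The +4 residue is read four residues downstream of the Q/R/N residue in
    the query's own (ungapped) coordinates, matching the biological
    definition rather than the alignment column.
    """
    query_seq = str(query_seq).upper()
    warnings: list[str] = []
    backbone = {p: _read_site(refmap, query_seq, p, warnings) for p in BACKBONE_CONTACT_POSITIONS}
    sidechain = {p: _read_site(refmap, query_seq, p, warnings) for p in SIDECHAIN_CONTACT_POSITIONS}
    qrn = _read_site(refmap, query_seq, QRN_POSITION, warnings)

    qrn_qidx = refmap.query_index(QRN_POSITION)
    if qrn_qidx is not None and qrn_qidx + 4 <= len(query_seq):
        plus4 = query_seq[qrn_qidx + 4 - 1]
    else:
        plus4 = _read_site(refmap, query_seq, PLUS4_POSITION, warnings)

    m3 = "".join(
        _read_site(refmap, query_seq, M3_MOTIF_START + i, warnings)[:1]
        if refmap.status(M3_MOTIF_START + i) != UNMAPPED
        else "?"
        for i in range(9)
    )
    lurcher = _read_site(refmap, query_seq, LURCHER_POSITION, warnings)
    siteG = "".join(
        _read_site(refmap, query_seq, p, warnings)[:1]
        if refmap.status(p) != UNMAPPED
        else "?"
        for p in SITE_G_POSITIONS
    )

    profile = SiteProfile(
        query_id=refmap.query_id,
        backbone=backbone,
        sidechain=sidechain,
        qrn=qrn,
        plus4=plus4,
        m3_motif=m3,
        lurcher=lurcher,
        siteG=siteG,
        warnings=warnings,
    )
    return profile


def predict_ligand(profile: SiteProfile) -> LigandPrediction:
    """Apply the residue rules for glutamate vs. glycine/D-serine specificity."""
    r653 = profile.sidechain.get(653, UNMAPPED)
    r655 = profile.sidechain.get(655, UNMAPPED)
    r732 = profile.sidechain.get(732, UNMAPPED)

    warnings: list[str] = []
    if profile.backbone.get(705) != "D":
        warnings.append("missing_D705")
    if profile.backbone.get(485) != "R":
        warnings.append("missing_R485")
    for r, pos in ((r653, 653), (r655, 655), (r732, 732)):
        if r in (GAP, UNMAPPED):
            warnings.append(f"gap_at_site_{pos}")

    if r653 in GLUTAMATE_653 and r655 in GLUTAMATE_655 and r732 in GLUTAMATE_732:
        label = "glutamate"
    elif r653 in GLYCINE_653 and r655 in GLYCINE_655 and r732 in GLYCINE_732:
        label = "glycine/D-serine"
    else:
        label = "unpredictable"
    return LigandPrediction(label=label, warnings=warnings)


def annotate_fasta(path, reference_seq: str | None = None, min_coverage: float = 0.3):
    """Annotate every record of a FASTA file; returns a pandas DataFrame.

    One row per query with the residues at all deterministic positions,
    the specificity call, and any warnings (semicolon-joined).
    """
    import pandas as pd

    rows = []
    for record in SeqIO.parse(str(path), "fasta"):
        refmap = map_to_reference(
            str(record.seq), reference_seq, query_id=record.id, min_coverage=min_coverage
        )
        profile = extract_sites(refmap, str(record.seq))
        pred = predict_ligand(profile)
        row = {"query_id": record.id, "coverage": round(refmap.coverage, 3)}
        row.update({f"pos{p}": r for p, r in sorted({**profile.backbone, **profile.sidechain}.items())})
        row.update(
            {
                "qrn": profile.qrn,
                "plus4": profile.plus4,
                "m3_motif": profile.m3_motif,
                "lurcher": profile.lurcher,
                "siteG": profile.siteG,
                "prediction": pred.label,
                "warnings": ";".join(pred.warnings + profile.warnings),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
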
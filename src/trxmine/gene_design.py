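"""Synthesizable gene design: N-terminus handling, codon optimization with
restriction-site exclusion, insert assembly, and protein properties.

Codon optimization follows the one-amino-acid-one-codon rule: every residue
gets the host's most frequent codon (CAI-maximal under this rule), then any
occurrence of a forbidden restriction motif inside the cloning insert is
repaired by swapping overlapping codons to synonymous alternatives with the
smallest possible frequency loss.  The insert places the CDS between an NdeI
site (whose ATG is the start codon) and an EcoRI site after the stop codon,
so those two junction sites — and only those — are allowed to remain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .errors import DataError, ParseError
from .family_mining import SequenceRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
ALTERNATIVE_STARTS = set("MLIV")

DEFAULT_FORBIDDEN_SITES = {
    "NdeI": "CATATG",
    "EcoRI": "GAATTC",
    "BamHI": "GGATCC",
}

FLANK_5 = "CAT"  # completes CAT + ATG -> NdeI at the 5' junction
FLANK_3 = "GAATTC"  # EcoRI appended after the stop codon


@dataclass
class CodonUsageTable:
    """Per-amino-acid codon frequencies, descending; stops under '*'."""

    codons: dict[str, list[tuple[str, float]]]

    def __post_init__(self) -> None:
        for aa in STANDARD_AA + "*":
            if aa not in self.codons or not self.codons[aa]:
                raise DataError(f"codon table missing amino acid {aa!r}")
        normalised = {}
        for aa, entries in self.codons.items():
            for codon, freq in entries:
                if len(codon) != 3 or set(codon) - set("ACGT"):
                    raise DataError(f"invalid codon {codon!r} for {aa!r}")
                if freq < 0:
                    raise DataError(f"negative frequency for {codon!r}")
            total = sum(f for _, f in entries)
            if total <= 0:
                raise DataError(f"zero total frequency for {aa!r}")
            entries = [(c, f / total) for c, f in entries]
            normalised[aa] = sorted(entries, key=lambda cf: (-cf[1], cf[0]))
        self.codons = normalised

    def top(self, aa: str) -> str:
        return self.codons[aa][0][0]

    def frequency(self, aa: str, codon: str) -> float:
        for c, f in self.codons[aa]:
            if c == codon:
                return f
        raise DataError(f"codon {codon!r} not listed for {aa!r}")

    def synonyms(self, aa: str) -> list[tuple[str, float]]:
        return list(self.codons[aa])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodonUsageTable":
        df = pd.read_csv(path, sep="\t", dtype={"amino_acid": str, "codon": str})
        for col in ("amino_acid", "codon", "frequency"):
            if col not in df.columns:
                raise ParseError(f"codon table missing column {col!r}")
        codons: dict[str, list[tuple[str, float]]] = {}
        for row in df.itertuples(index=False):
            codons.setdefault(row.amino_acid, []).append(
                (row.codon.upper(), float(row.frequency))
            )
        return cls(codons=codons)

    @classmethod
    def ecoli_default(cls) -> "CodonUsageTable":
        ref = resources.files("trxmine.data") / "ecoli_k12_codon_usage.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass
class GeneDesign:
    protein_id: str
    cds: str
    insert: str
    substitutions: list[tuple[int, str, str, str]] = field(default_factory=list)
    feasible: bool = True


# ---------------------------------------------------------------------------
# N-terminus handling


def correct_start(
    record: SequenceRecord,
    homolog_start_positions: list[int],
    majority_fraction: float = 0.5,
) -> SequenceRecord:
    """Trim to an internal start when a majority of homolog starts map there.

    If more than ``majority_fraction`` of the homolog start offsets agree on
    one internal position whose residue can act as a start (M, or the
    alternative starts L/I/V), the sequence is trimmed to that position and
    its first residue set to M.  Otherwise the record is returned unchanged.
    """
    if not homolog_start_positions:
        return record
    n = len(record.residues)
    for pos in homolog_start_positions:
        if not (1 <= pos <= n):
            raise DataError(f"start offset {pos} beyond sequence {record.id!r}")
    counts: dict[int, int] = {}
    for pos in homolog_start_positions:
        counts[pos] = counts.get(pos, 0) + 1
    pos, votes = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    if pos == 1 or votes / len(homolog_start_positions) <= majority_fraction:
        return record
    if record.residues[pos - 1] not in ALTERNATIVE_STARTS:
        return record
    return SequenceRecord(
        id=record.id,
        residues="M" + record.residues[pos:],
        description=record.description,
        has_start=record.has_start,
        has_stop=record.has_stop,
    )


def remove_signal_peptide(
    record: SequenceRecord, cleavage_position: int
) -> SequenceRecord:
    """Drop the signal peptide (residues 1..cleavage_position); prepend M if
    the mature protein does not already start with one."""
    if not (1 <= cleavage_position < len(record.residues)):
        raise DataError(
            f"cleavage position {cleavage_position} out of range for {record.id!r}"
        )
    mature = record.residues[cleavage_position:]
    if not mature.startswith("M"):
        mature = "M" + mature
    return SequenceRecord(
        id=record.id,
        residues=mature,
        description=record.description,
        has_start=record.has_start,
        has_stop=record.has_stop,
    )


# ---------------------------------------------------------------------------
# Codon optimization


def _find_motifs(dna: str, motifs: dict[str, str]) -> list[tuple[str, int]]:
    """All (motif name, 0-based start) occurrences in dna."""
    found = []
    for name, motif in motifs.items():
        start = dna.find(motif)
        while start != -1:
            found.append((name, start))
            start = dna.find(motif, start + 1)
    return sorted(found, key=lambda x: (x[1], x[0]))


def _violations(codons: list[str], motifs: dict[str, str]) -> list[tuple[str, int]]:
    """Forbidden-motif occurrences in the insert context, excluding the two
    sanctioned junction sites."""
    context = FLANK_5 + "".join(codons) + FLANK_3
    out = []
    for name, start in _find_motifs(context, motifs):
        motif = motifs[name]
        # the NdeI formed at the 5' junction and the EcoRI at the 3' junction
        # are the cloning sites themselves
        if name == "NdeI" and start == 0:
            continue
        if name == "EcoRI" and start == len(context) - len(motif):
            continue
        out.append((name, start))
    return out


def optimize_codons(
    protein: str,
    table: CodonUsageTable | None = None,
    forbidden: dict[str, str] | None = None,
    protein_id: str = "",
    stop_codon: str | None = None,
) -> GeneDesign:
    """Design a CDS for ``protein`` with top-frequency codons and no internal
    forbidden restriction site.

    The scan runs over the full insert context (CAT flank + CDS + stop +
    GAATTC flank) so junction-straddling sites are caught.  Each offending
    occurrence is repaired by the synonymous swap (over at most the three
    codons overlapping the 6-mer, single swaps first, then pairs/triples)
    that destroys it, creates no new occurrence, and loses the least codon
    frequency.  ``feasible`` is False when no combination clears a site.
    """
    if not protein:
        raise DataError("empty protein")
    if table is None:
        table = CodonUsageTable.ecoli_default()
    if forbidden is None:
        forbidden = dict(DEFAULT_FORBIDDEN_SITES)
    for aa in protein:
        if aa not in table.codons:
            raise DataError(f"residue {aa!r} absent from codon table")

    seq = protein if protein.startswith("M") else "M" + protein
    codons = [table.top(aa) for aa in seq]
    aas = list(seq) + ["*"]
    codons.append(stop_codon if stop_codon else table.top("*"))

    substitutions: list[tuple[int, str, str, str]] = []
    feasible = True
    guard = 0
    while True:
        violations = _violations(codons, forbidden)
        if not violations:
            break
        guard += 1
        if guard > 10 * len(codons):
            feasible = False
            break
        name, start = violations[0]
        motif_len = len(forbidden[name])
        # codon indices overlapping the motif span within the context
        first = max(0, (start - len(FLANK_5)) // 3)
        last = min(len(codons) - 1, (start + motif_len - 1 - len(FLANK_5)) // 3)
        window = [
            i for i in range(first, last + 1)
            if len(table.synonyms(aas[i])) > 1
        ]
        repair = _search_repair(codons, aas, window, name, start, forbidden, table)
        if repair is None:
            feasible = False
            break
        for idx, new_codon in repair:
            substitutions.append(
                (idx, codons[idx], new_codon, f"{name} site at insert position {start + 1}")
            )
            codons[idx] = new_codon

    cds = "".join(codons)
    insert = FLANK_5 + cds + FLANK_3
    design = GeneDesign(
        protein_id=protein_id,
        cds=cds,
        insert=insert,
        substitutions=substitutions,
        feasible=feasible,
    )
    return design


def _search_repair(
    codons: list[str],
    aas: list[str],
    window: list[int],
    name: str,
    start: int,
    forbidden: dict[str, str],
    table: CodonUsageTable,
):
    """Bounded backtracking over the codons overlapping one motif occurrence.

    Tries all non-empty swap combinations over the window (size <= 3),
    ordered by total frequency loss, and returns the first that removes the
    occurrence without creating any new violation elsewhere.
    """
    n_before = len(_violations(codons, forbidden))
    candidates = []
    for r in range(1, len(window) + 1):
        for combo in itertools.combinations(window, r):
            alt_lists = []
            for idx in combo:
                current = codons[idx]
                alts = [
                    (c, table.frequency(aas[idx], current) - f)
                    for c, f in table.synonyms(aas[idx])
                    if c != current
                ]
                alt_lists.append([(idx, c, loss) for c, loss in alts])
            for choice in itertools.product(*alt_lists):
                loss = sum(item[2] for item in choice)
                candidates.append((loss, [(item[0], item[1]) for item in choice]))
    candidates.sort(key=lambda x: (x[0], x[1]))
    motif = forbidden[name]
    for _, swaps in candidates:
        trial = list(codons)
        for idx, new_codon in swaps:
            trial[idx] = new_codon
        trial_viols = _violations(trial, forbidden)
        context = FLANK_5 + "".join(trial) + FLANK_3
        if context[start : start + len(motif)] == motif:
            continue  # this occurrence survives
        if len(trial_viols) < n_before:
            return swaps
    return None


def assemble_insert(cds: str, forbidden: dict[str, str] | None = None) -> str:
    """CAT + cds + GAATTC, verified to contain exactly the two junction sites.

    The cds must start with ATG and end with a stop codon.  Any other
    forbidden-motif occurrence raises, signalling that optimization must be
    rerun with flanks in view (optimize_codons does this by default).
    """
    if forbidden is None:
        forbidden = dict(DEFAULT_FORBIDDEN_SITES)
    if not cds.startswith("ATG"):
        raise DataError("cds must start with ATG")
    if cds[-3:] not in ("TAA", "TGA", "TAG"):
        raise DataError("cds must end with a stop codon")
    insert = FLANK_5 + cds + FLANK_3
    occurrences = _find_motifs(insert, forbidden)
    sanctioned = {("NdeI", 0), ("EcoRI", len(insert) - 6)}
    extra = [o for o in occurrences if o not in sanctioned]
    if extra:
        raise DataError(f"internal forbidden site(s) in insert: {extra}")
    return insert


def translate_cds(cds: str) -> str:
    """Translate a CDS (without the trailing stop) back to protein."""
    if len(cds) % 3:
        raise DataError("cds length not a multiple of 3")
    prot = str(Seq(cds).translate())
    if not prot.endswith("*"):
        raise DataError("cds does not end with a stop codon")
    return prot[:-1]


# ---------------------------------------------------------------------------
# Protein properties


def protein_properties(record: SequenceRecord) -> dict[str, float]:
    """Average molecular mass (Da) and 280-nm molar extinction coefficients.

    epsilon_reduced = 5500 * nTrp + 1490 * nTyr; the all-cystine form adds
    125 per cystine (Cys pair).  Average (not monoisotopic) residue masses.
    """
    seq = record.residues
    bad = set(seq) - set(STANDARD_AA)
    if bad:
        raise DataError(f"nonstandard residues {sorted(bad)} in {record.id!r}")
    analysis = ProteinAnalysis(seq)
    eps_reduced, eps_cystine = analysis.molar_extinction_coefficient()
    return {
        "mass_da": analysis.molecular_weight(),
        "epsilon_reduced": float(eps_reduced),
        "epsilon_cystine": float(eps_cystine),
    }
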
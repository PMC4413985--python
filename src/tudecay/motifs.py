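"""3'UTR cis-element scanning and stability-set enrichment.

A motif is a degenerate RNA pattern over an IUPAC subset plus explicit bracket
classes, e.g. ``UGUA[AUC]AUA`` for the Pumilio recognition element (PRE).
Scanning counts all (possibly overlapping) matches on the sense strand only —
the mRNA context — and a gene "contains" the element iff its count reaches
``min_count`` (default 1, i.e. at least one occurrence in the 3'UTR).

Enrichment compares element frequency between a stability-defined gene set and
a background universe: both the frequency ratio (the field's informal "odds
ratio" for this kind of comparison) and the classical odds ratio are reported,
with a two-sided Fisher exact p-value on the 2x2 table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

__all__ = [
    "MotifSpec",
    "scan_motif",
    "scan_all",
    "builtin_motifs",
    "stability_strata",
    "element_enrichment",
    "EnrichmentResult",
]

#: IUPAC degeneracy codes on the RNA alphabet.
IUPAC_RNA = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "W": "AU", "S": "CG", "M": "AC", "K": "GU", "R": "AG", "Y": "CU",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


@dataclass(frozen=True)
class MotifSpec:
    """A named degenerate motif. ``pattern`` may mix IUPAC codes and [..] classes."""

    name: str
    pattern: str
    min_count: int = 1

    def positions(self) -> list[str]:
        """Parse the pattern into one allowed-character set per position."""
        out: list[str] = []
        i = 0
        pat = self.pattern.upper().replace("T", "U")
        while i < len(pat):
            ch = pat[i]
            if ch == "[":
                j = pat.find("]", i)
                if j < 0:
                    raise ConfigError(f"motif {self.name}: unterminated '[' in pattern")
                chars = pat[i + 1 : j]
                if not chars or set(chars) - set("ACGU"):
                    raise ConfigError(
                        f"motif {self.name}: bracket class must be literal A/C/G/U"
                    )
                out.append("".join(sorted(set(chars))))
                i = j + 1
            elif ch in IUPAC_RNA:
                out.append(IUPAC_RNA[ch])
                i += 1
            else:
                raise ConfigError(f"motif {self.name}: illegal pattern character {ch!r}")
        if len(out) < 5:
            raise ConfigError(f"motif {self.name}: pattern shorter than 5 positions")
        return out

    def regex(self) -> re.Pattern:
        # lookahead so overlapping occurrences are all counted
        body = "".join(p if len(p) == 1 else f"[{p}]" for p in self.positions())
        return re.compile(f"(?={body})")

    def expansions(self) -> list[str]:
        """All literal words matching the pattern (small motifs only)."""
        words = [""]
        for chars in self.positions():
            words = [w + c for w in words for c in chars]
        return words


def scan_motif(sequence: str, spec: MotifSpec) -> tuple[int, list[int]]:
    """Count matches of ``spec`` in an RNA sequence; 0-based positions."""
    positions = [m.start() for m in spec.regex().finditer(sequence)]
    return len(positions), positions


def scan_all(utrs: dict[str, str], specs: list[MotifSpec]) -> pd.DataFrame:
    """Scan every UTR for every motif; one row per gene x motif."""
    rows = []
    for gene_id, seq in utrs.items():
        for spec in specs:
            count, positions = scan_motif(seq, spec)
            rows.append(
                {
                    "gene_id": gene_id,
                    "motif": spec.name,
                    "count": count,
                    "positions": ",".join(map(str, positions)),
                    "present": count >= spec.min_count,
                }
            )
    return pd.DataFrame(rows)


def builtin_motifs() -> list[MotifSpec]:
    """Built-in PRE / ARE / miR-124 seed motifs from the packaged data file."""
    path = resources.files("tudecay").joinpath("data/motifs.tsv")
    with path.open() as fh:
        table = pd.read_csv(fh, sep="\t", comment="#")
    return [MotifSpec(row["name"], row["pattern"]) for _, row in table.iterrows()]


def stability_strata(
    records: pd.DataFrame, low_max: float = 75.0, high_min: float = 80.0
) -> dict[str, set[str]]:
    """Split aggregated half-life records into low/high-stability gene sets.

    Low: mean half-life <= ``low_max`` min (inclusive); high: >= ``high_min``
    min.  Genes in the open interval between the bounds are excluded, so the
    sets are disjoint by construction.
    """
    if low_max >= high_min:
        raise ConfigError(f"low_max ({low_max}) must be < high_min ({high_min})")
    finite = records.loc[records["mean_t_half"].notna()]
    low = set(finite.loc[finite["mean_t_half"] <= low_max, "gene_id"])
    high = set(finite.loc[finite["mean_t_half"] >= high_min, "gene_id"])
    return {"low": low, "high": high}


@dataclass
class EnrichmentResult:
    motif: str
    set_hits: int
    set_size: int
    bg_hits: int
    bg_size: int
    frequency_ratio: float
    odds_ratio: float
    fisher_p: float


def element_enrichment(
    gene_set: set[str],
    background_set: set[str],
    hits: pd.DataFrame,
    motif: MotifSpec,
) -> EnrichmentResult:
    """Element presence enrichment of ``gene_set`` against ``background_set``.

    ``hits`` is the output of :func:`scan_all`.  The frequency ratio is
    (set hit fraction)/(background hit fraction); the classical odds ratio uses
    the 2x2 table with a Haldane 0.5 correction when any cell is zero.  The
    Fisher exact test is two-sided on set membership x element presence.
    """
    if not gene_set:
        raise DataError("empty gene set")
    sub = hits.loc[hits["motif"] == motif.name]
    present = set(sub.loc[sub["count"] >= motif.min_count, "gene_id"])

    set_size = len(gene_set)
    bg_size = len(background_set)
    set_hits = len(gene_set & present)
    bg_hits = len(background_set & present)

    a, b = set_hits, set_size - set_hits
    c, d = bg_hits, bg_size - bg_hits
    freq_ratio = (
        (set_hits / set_size) / (bg_hits / bg_size) if bg_hits > 0 else float("inf")
    )
    if min(a, b, c, d) == 0:
        ah, bh, ch, dh = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        ah, bh, ch, dh = a, b, c, d
    odds = (ah * dh) / (bh * ch)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(motif.name, set_hits, set_size, bg_hits, bg_size,
                            freq_ratio, odds, float(p))
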
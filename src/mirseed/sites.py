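"""miRNA binding-site scanning over 3' UTR sequences.

All geometry lives in one convention: sequences are RNA, 5'→3', with 1-based
inclusive UTR coordinates.  A scanning *register* is the UTR position that
would sit opposite miRNA nucleotide 1 in the antiparallel duplex; miRNA
nucleotide k then pairs UTR position ``register − k + 1``.

Site classes:

* canonical — Watson–Crick match to the seed (miRNA nt 2–7), classified
  maximally as 8mer > 7mer-m8 > 7mer-A1 > 6mer.  The A1 position requires a
  target adenosine regardless of miRNA nt 1 identity.
* offset 6mer — WC match to nt 3–8 with nt 2 unpaired (otherwise the locus
  is canonical and excluded).
* seed-mismatched / G:U wobble — exactly one of nt 2–7 non-WC; classified as
  a wobble when the offending pair is G:U in either orientation.
* G-bulge — a 7-nt target locus that becomes a perfect seed match upon
  deleting a guanosine bulged between the bases pairing nt 6 and nt 5.
* centered — ≥ 11 consecutive WC pairs fully covering miRNA nt 4–14 or
  5–15, excluding loci that also carry a canonical seed match.

3' pairing flags are evaluated at the site's fixed register, with no target
bulges or loops, and wobbles do not count as pairs: supplementary pairing is
≥ 3 contiguous WC pairs at miRNA positions 13–16, compensatory pairing
(imperfect-seed sites only) ≥ 4 contiguous pairs at positions 12–17.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .io import SequenceRecord, normalize_residues

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

CANONICAL_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
NONCANONICAL_CLASSES = ("offset6", "seed_mismatch", "gu_wobble", "gbulge", "centered")
SITE_CLASSES = CANONICAL_CLASSES + NONCANONICAL_CLASSES
MISMATCH_CLASSES = ("seed_mismatch", "gu_wobble")


@dataclass(frozen=True)
class BindingSite:
    """One detected site; start/end are 1-based inclusive on the UTR 5'→3'."""

    mirna: str
    utr: str
    site_class: str
    start: int
    end: int
    register: int  # UTR position opposite miRNA nt 1
    mismatch_pos: int | None = None
    supp3p: bool = False
    comp3p: bool = False


def _seq(x: SequenceRecord | str) -> str:
    return x.residues if isinstance(x, SequenceRecord) else normalize_residues(x)


def _name(x: SequenceRecord | str, default: str) -> str:
    return x.id if isinstance(x, SequenceRecord) else default


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement in RNA space."""
    s = _seq(seq) if seq else ""
    return "".join(COMPLEMENT[c] for c in reversed(s))


def _wc(mirna_base: str, target_base: str) -> bool:
    return COMPLEMENT[mirna_base] == target_base


def _wobble(mirna_base: str, target_base: str) -> bool:
    return (mirna_base, target_base) in (("G", "U"), ("U", "G"))


def _pairs(mir: str, utr: str, register: int, k: int) -> bool:
    """Does miRNA nt k WC-pair at this register (False off either end)?"""
    pos = register - k + 1
    if k < 1 or k > len(mir) or pos < 1 or pos > len(utr):
        return False
    return _wc(mir[k - 1], utr[pos - 1])


def scan_canonical(mirna: SequenceRecord | str, utr: SequenceRecord | str) -> list[BindingSite]:
    """All canonical seed-matched loci, maximally classified.

    Coordinates span every matched target position, including the A1
    adenosine when it is part of the class.
    """
    mir, tgt = _seq(mirna), _seq(utr)
    mname, uname = _name(mirna, "miRNA"), _name(utr, "utr")
    if len(mir) < 8:
        raise ValueError("canonical scan needs a miRNA of length >= 8")
    sites = []
    for register in range(7, len(tgt) + 2):
        if not all(_pairs(mir, tgt, register, k) for k in range(2, 8)):
            continue
        m8 = _pairs(mir, tgt, register, 8)
        a1 = register <= len(tgt) and tgt[register - 1] == "A"
        if m8 and a1:
            cls, start, end = "8mer", register - 7, register
        elif m8:
            cls, start, end = "7mer-m8", register - 7, register - 1
        elif a1:
            cls, start, end = "7mer-A1", register - 6, register
        else:
            cls, start, end = "6mer", register - 6, register - 1
        sites.append(BindingSite(mname, uname, cls, start, end, register))
    return sites


def scan_offset6(mirna: SequenceRecord | str, utr: SequenceRecord | str) -> list[BindingSite]:
    """Offset 6mer loci: WC match to miRNA nt 3–8, nt 2 not pairing."""
    mir, tgt = _seq(mirna), _seq(utr)
    mname, uname = _name(mirna, "miRNA"), _name(utr, "utr")
    if len(mir) < 8:
        raise ValueError("offset-6mer scan needs a miRNA of length >= 8")
    sites = []
    for register in range(8, len(tgt) + 3):
        if not all(_pairs(mir, tgt, register, k) for k in range(3, 9)):
            continue
        if _pairs(mir, tgt, register, 2):  # locus is canonical
            continue
        sites.append(
            BindingSite(mname, uname, "offset6", register - 7, register - 2, register)
        )
    return sites


def scan_mismatch_wobble(mirna: SequenceRecord | str, utr: SequenceRecord | str) -> list[BindingSite]:
    """Seed loci where exactly one of nt 2–7 is non-WC.

    The site is a G:U wobble when the single offending pair is G:U in either
    orientation, a seed mismatch otherwise; ``mismatch_pos`` records the
    miRNA seed position involved.
    """
    mir, tgt = _seq(mirna), _seq(utr)
    mname, uname = _name(mirna, "miRNA"), _name(utr, "utr")
    if len(mir) < 7:
        raise ValueError("seed-mismatch scan needs a miRNA of length >= 7")
    sites = []
    for register in range(7, len(tgt) + 2):
        bad = [k for k in range(2, 8) if not _pairs(mir, tgt, register, k)]
        if len(bad) != 1:
            continue
        k = bad[0]
        pos = register - k + 1
        if pos < 1 or pos > len(tgt):  # truncated seed window, not a mismatch
            continue
        wob = _wobble(mir[k - 1], tgt[pos - 1])
        sites.append(
            BindingSite(
                mname, uname,
                "gu_wobble" if wob else "seed_mismatch",
                register - 6, register - 1, register,
                mismatch_pos=k,
            )
        )
    return sites


def scan_gbulge(mirna: SequenceRecord | str, utr: SequenceRecord | str) -> list[BindingSite]:
    """G-bulge loci: 7-nt windows equal to the perfect seed target with one
    extra G between the bases pairing miRNA nt 6 and nt 5.

    Equivalent deletions inside a G run collapse to one site per window.
    """
    mir, tgt = _seq(mirna), _seq(utr)
    mname, uname = _name(mirna, "miRNA"), _name(utr, "utr")
    if len(mir) < 7:
        raise ValueError("G-bulge scan needs a miRNA of length >= 7")
    perfect = reverse_complement(mir[1:7])  # [c7 c6 c5 c4 c3 c2]
    bulged = perfect[:2] + "G" + perfect[2:]
    sites = []
    for start in range(1, len(tgt) - 5):
        if tgt[start - 1 : start + 6] == bulged:
            # nt2 pairs the window's last base; nt1 would pair one further 3'
            sites.append(
                BindingSite(mname, uname, "gbulge", start, start + 6, start + 7)
            )
    return sites


def _wc_runs(mir: str, tgt: str, register: int) -> list[tuple[int, int]]:
    """Maximal runs [k_lo, k_hi] of consecutive WC-paired miRNA positions."""
    runs = []
    k = 1
    while k <= len(mir):
        if _pairs(mir, tgt, register, k):
            lo = k
            while k <= len(mir) and _pairs(mir, tgt, register, k):
                k += 1
            runs.append((lo, k - 1))
        else:
            k += 1
    return runs


def scan_centered(mirna: SequenceRecord | str, utr: SequenceRecord | str) -> list[BindingSite]:
    """Centered loci: >= 11 consecutive WC pairs covering nt 4–14 or 5–15."""
    mir, tgt = _seq(mirna), _seq(utr)
    mname, uname = _name(mirna, "miRNA"), _name(utr, "utr")
    if len(mir) < 15:
        warnings.warn("miRNA shorter than 15 nt: centered sites undefined")
        return []
    sites = []
    seen: set[tuple[int, int]] = set()
    for register in range(1, len(tgt) + len(mir)):
        if all(_pairs(mir, tgt, register, k) for k in range(2, 8)):
            continue  # canonical locus, excluded
        for lo, hi in _wc_runs(mir, tgt, register):
            if (lo <= 4 and hi >= 14) or (lo <= 5 and hi >= 15):
                start, end = register - hi + 1, register - lo + 1
                if (start, end) not in seen:
                    seen.add((start, end))
                    sites.append(
                        BindingSite(mname, uname, "centered", start, end, register)
                    )
    return sites


def flag_3prime_pairing(
    site: BindingSite, mirna: SequenceRecord | str, utr: SequenceRecord | str
) -> BindingSite:
    """Set supp3p/comp3p on a detected site at its fixed register.

    Runs are contiguous WC pairs (no wobbles, no loops); positions truncated
    at the UTR 5' end do not pair.  Compensatory pairing applies only to
    imperfect-seed (mismatch/wobble) sites.
    """
    mir, tgt = _seq(mirna), _seq(utr)

    def longest_run(k_lo: int, k_hi: int) -> int:
        best = cur = 0
        for k in range(k_lo, k_hi + 1):
            cur = cur + 1 if _pairs(mir, tgt, site.register, k) else 0
            best = max(best, cur)
        return best

    supp = longest_run(13, 16) >= 3
    comp = site.site_class in MISMATCH_CLASSES and longest_run(12, 17) >= 4
    return replace(site, supp3p=supp, comp3p=comp)


def scan_pair(
    mirna: SequenceRecord | str,
    utr: SequenceRecord | str,
    classes: Sequence[str] = SITE_CLASSES,
) -> list[BindingSite]:
    """Run every requested scanner on one (miRNA, UTR) pair and attach
    3'-pairing flags; sites sorted by start position."""
    sites: list[BindingSite] = []
    if any(c in CANONICAL_CLASSES for c in classes):
        sites += [s for s in scan_canonical(mirna, utr) if s.site_class in classes]
    if "offset6" in classes:
        sites += scan_offset6(mirna, utr)
    if any(c in MISMATCH_CLASSES for c in classes):
        sites += [s for s in scan_mismatch_wobble(mirna, utr) if s.site_class in classes]
    if "gbulge" in classes:
        sites += scan_gbulge(mirna, utr)
    if "centered" in classes:
        sites += scan_centered(mirna, utr)
    sites = [flag_3prime_pairing(s, mirna, utr) for s in sites]
    # identical (class, start) duplicates collapse; different registers stay
    dedup: dict[tuple[str, int, int], BindingSite] = {}
    for s in sites:
        dedup.setdefault((s.site_class, s.start, s.end), s)
    return sorted(dedup.values(), key=lambda s: (s.start, s.end, s.site_class))


def annotate_combination(
    mirna: SequenceRecord | str,
    utr: SequenceRecord | str,
    sites: Iterable[BindingSite] | None = None,
) -> dict:
    """Per-(miRNA, UTR) site census: counts per class, canonical flags, and
    with-3'-pairing counts.  Site-level canonical classes are exclusive, so
    the per-class canonical counts sum to the total canonical site count;
    combination-level class membership is non-exclusive across classes."""
    if sites is None:
        sites = scan_pair(mirna, utr)
    sites = list(sites)
    counts = {cls: sum(1 for s in sites if s.site_class == cls) for cls in SITE_CLASSES}
    n_canonical = sum(counts[c] for c in CANONICAL_CLASSES)
    supp = {
        cls: sum(1 for s in sites if s.site_class == cls and s.supp3p)
        for cls in SITE_CLASSES
    }
    ann = {
        "mirna": _name(mirna, "miRNA"),
        "utr": _name(utr, "utr"),
        **{f"n_{cls.replace('-', '_').lower()}": counts[cls] for cls in SITE_CLASSES},
        "n_canonical": n_canonical,
        "any_canonical": n_canonical > 0,
        "multiple_canonical": n_canonical >= 2,
        "n_canonical_supp3p": sum(supp[c] for c in CANONICAL_CLASSES),
        **{f"n_{cls.replace('-', '_').lower()}_supp3p": supp[cls] for cls in NONCANONICAL_CLASSES},
        "n_mismatch_comp3p": sum(
            1 for s in sites if s.site_class in MISMATCH_CLASSES and s.comp3p
        ),
    }
    return ann


def sites_to_frame(sites: Iterable[BindingSite]) -> pd.DataFrame:
    rows = [
        (s.mirna, s.utr, s.site_class, s.start, s.end, s.mismatch_pos, s.supp3p, s.comp3p)
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=["mirna", "utr", "site_class", "start", "end", "mismatch_pos",
                 "supp3p", "comp3p"],
    )


def annotate_pairs(
    mirnas: Sequence[SequenceRecord],
    utrs: Sequence[SequenceRecord],
    classes: Sequence[str] = SITE_CLASSES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan the full cross of miRNAs × UTRs.

    Returns (site table, per-combination annotation table).
    """
    all_sites: list[BindingSite] = []
    annotations: list[dict] = []
    for m in mirnas:
        for u in utrs:
            sites = scan_pair(m, u, classes=classes)
            all_sites.extend(sites)
            annotations.append(annotate_combination(m, u, sites))
    return sites_to_frame(all_sites), pd.DataFrame(annotations)


def sites_to_bed(sites: Iterable[BindingSite]) -> pd.DataFrame:
    """BED6 per UTR; the 0-based half-open conversion happens here only."""
    rows = [
        (s.utr, s.start - 1, s.end, f"{s.mirna}|{s.site_class}", 0, "+")
        for s in sites
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
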
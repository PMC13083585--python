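"""Report deduplication and deletion-list removal.

A FAERS case (CASEID) accumulates report versions (PRIMARYID) over time.
Deduplication keeps, per case, the version with the largest FDA receipt
date; among equal receipt dates, the largest numeric PRIMARYID wins.
Versions whose FDA_DT lacks day precision sort below every day-precision
version (and among themselves by PRIMARYID), so an undated version can
never displace a dated one.

Deletion lists are applied after deduplication: any retained report whose
CASEID appears in any quarter's deletion list is removed, cumulatively
across quarters.  Unknown CASEIDs in deletion lists are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .faers_io import numeric_id_key


@dataclass
class DedupResult:
    retained_primaryids: set = field(default_factory=set)
    removed_as_duplicate: int = 0
    removed_by_deletion: int = 0

    @property
    def n_retained(self) -> int:
        return len(self.retained_primaryids)


def deduplicate(demo: list) -> DedupResult:
    """Keep exactly one report version per CASEID.

    Selection per case: maximal FDA_DT (day precision outranks partial or
    missing); ties broken by maximal numeric PRIMARYID.  Raises ValueError
    on a duplicated PRIMARYID, which violates the FAERS key.
    """
    seen: set = set()
    best: dict = {}
    n = 0
    for rec in demo:
        n += 1
        if rec.primaryid in seen:
            raise ValueError(f"duplicate primaryid {rec.primaryid!r} in input")
        seen.add(rec.primaryid)
        key = (rec.fda_dt.sort_key(), numeric_id_key(rec.primaryid))
        cur = best.get(rec.caseid)
        if cur is None or key > cur[0]:
            best[rec.caseid] = (key, rec.primaryid)
    retained = {pid for _, pid in best.values()}
    return DedupResult(
        retained_primaryids=retained,
        removed_as_duplicate=n - len(retained),
    )


def apply_deletions(result: DedupResult, demo: list, deletion_caseids: set) -> DedupResult:
    """Remove retained reports whose CASEID is on a deletion list.

    Applied after :func:`deduplicate`; counts are accumulated into a new
    DedupResult so input size conservation still holds.
    """
    caseid_of = {rec.primaryid: rec.caseid for rec in demo}
    retained = {
        pid for pid in result.retained_primaryids
        if caseid_of.get(pid) not in deletion_caseids
    }
    n_deleted = len(result.retained_primaryids) - len(retained)
    return DedupResult(
        retained_primaryids=retained,
        removed_as_duplicate=result.removed_as_duplicate,
        removed_by_deletion=result.removed_by_deletion + n_deleted,
    )


def dedup_bundles(bundles: list) -> tuple:
    """Deduplicate a multi-quarter extract and apply all deletion lists.

    Returns ``(DedupResult, all_demo)`` where ``all_demo`` is the pooled
    DEMO list across quarters (versions of one case may span quarters).
    """
    all_demo: list = []
    deletions: set = set()
    for b in bundles:
        all_demo.extend(b.demo)
        deletions |= set(b.deletion_caseids)
    result = deduplicate(all_demo)
    result = apply_deletions(result, all_demo, deletions)
    return result, all_demo
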
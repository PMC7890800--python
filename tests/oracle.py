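"""Independent brute-force oracle for the per-sample metric panel.

Re-derives every SampleSiteMetrics field from a raw observation list by
exhaustive iteration and hand-rolled order statistics (no numpy), so the
production path and the oracle share no code.
"""

from __future__ import annotations

from somafilt.metrics import ReadObservation


def brute_median(values):
    if not values:
        return None
    s = sorted(values)
    n = len(s)
    mid = n // 2
    if n % 2 == 1:
        return float(s[mid])
    return (s[mid - 1] + s[mid]) / 2.0


def brute_mad(values):
    if not values:
        return None
    m = brute_median(values)
    return brute_median([abs(v - m) for v in values])


def brute_summary(observations, site) -> dict:
    alt = [o for o in observations if o.base == site.alt]
    ref = [o for o in observations if o.base == site.ref]
    depth = len(observations)
    alt_n, ref_n = len(alt), len(ref)

    def frac(num, den):
        return num / den if den else None

    alt_bq = [o.base_quality for o in alt if o.base_quality is not None]
    ref_bq = [o.base_quality for o in ref if o.base_quality is not None]
    alt_pos = [o.query_pos for o in alt if o.query_pos is not None]
    alt_dist = [min(o.query_pos, o.read_length - 1 - o.query_pos) for o in alt
                if o.query_pos is not None]
    alt_nm = [max(o.nm - 1, 0) for o in alt if o.nm is not None]
    return {
        "depth": depth,
        "ref_count": ref_n,
        "alt_count": alt_n,
        "other_count": depth - alt_n - ref_n,
        "vaf": frac(alt_n, depth),
        "median_bq_alt": brute_median(alt_bq),
        "median_bq_ref": brute_median(ref_bq),
        "median_mq_alt": brute_median([o.mapping_quality for o in alt]),
        "median_mq_all": brute_median([o.mapping_quality for o in observations]),
        "alt_fwd": len([o for o in alt if not o.is_reverse]),
        "alt_rev": len([o for o in alt if o.is_reverse]),
        "ref_fwd": len([o for o in ref if not o.is_reverse]),
        "ref_rev": len([o for o in ref if o.is_reverse]),
        "median_dist_readend_alt": brute_median(alt_dist),
        "mad_pos_alt": brute_mad(alt_pos),
        "softclip_frac_alt": frac(len([o for o in alt if o.has_softclip]), alt_n),
        "mean_excess_nm_alt": (sum(alt_nm) / len(alt_nm)) if alt_nm else None,
        "mq0_frac": frac(len([o for o in observations if o.mapping_quality == 0]), depth),
        "near_indel_frac": frac(len([o for o in observations if o.near_indel]), depth),
        "improper_pair_frac_alt": frac(len([o for o in alt if not o.properly_paired]), alt_n),
    }


def random_pileup(rng, ref="A", alt="T"):
    """A random observation list mixing ref/alt/other/DEL evidence with
    missing qualities and NM tags, MQ0 reads and improper pairs."""
    n = int(rng.integers(0, 40))
    obs = []
    for _ in range(n):
        kind = rng.choice(["ref", "alt", "other", "del"], p=[0.5, 0.3, 0.1, 0.1])
        read_len = int(rng.integers(50, 151))
        if kind == "del":
            base, qpos, bq = "DEL", None, None
        else:
            base = {"ref": ref, "alt": alt, "other": "G"}[kind]
            qpos = int(rng.integers(0, read_len))
            bq = None if rng.random() < 0.1 else int(rng.integers(2, 42))
        obs.append(
            ReadObservation(
                base=base,
                base_quality=bq,
                mapping_quality=int(rng.choice([0, 20, 40, 60], p=[0.1, 0.2, 0.3, 0.4])),
                is_reverse=bool(rng.integers(0, 2)),
                query_pos=qpos,
                read_length=read_len,
                has_softclip=bool(rng.random() < 0.2),
                nm=None if rng.random() < 0.15 else int(rng.integers(0, 8)),
                properly_paired=bool(rng.random() < 0.9),
                near_indel=bool(rng.random() < 0.2),
            )
        )
    return obs
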
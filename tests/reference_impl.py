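"""Naive single-pass reference implementations used as independent oracles.

Everything here is written with plain Python loops and the standard
library only (no numpy/pandas vectorisation, no sklearn), directly from
the feature definitions, so that agreement with the package is a real
cross-check rather than a tautology.
"""

import math
import statistics


def ref_accel_stats(samples):
    """samples: list of (x, y, z) tuples."""
    mags = [math.sqrt(x * x + y * y + z * z) for x, y, z in samples]
    out = {
        "accel_min": min(mags), "accel_max": max(mags),
        "accel_mean": statistics.fmean(mags),
        "accel_median": statistics.median(mags),
    }
    out["accel_sd"] = statistics.stdev(mags) if len(mags) >= 2 else None
    return out


def ref_activity(labels):
    counts = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    top = max(counts.values())
    return {
        "n_activities": len(counts),
        "most_common_activity": min(k for k, v in counts.items() if v == top),
        "n_activity_changes": sum(1 for a, b in zip(labels, labels[1:])
                                  if a != b),
    }


def ref_haversine(lat1, lon1, lat2, lon2, radius=6_371_000.0):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = math.radians(lat2 - lat1)
    dl = math.radians(lon2 - lon1)
    a = (math.sin(dp / 2) ** 2
         + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2)
    return 2 * radius * math.asin(math.sqrt(a))


def ref_travel_distance(coords):
    return sum(ref_haversine(*a, *b) for a, b in zip(coords, coords[1:]))


def ref_entropy(dwells):
    total = sum(dwells)
    ps = [d / total for d in dwells if d > 0]
    return -sum(p * math.log(p) for p in ps)


def ref_radius_of_gyration(centroids, dwells):
    total = sum(dwells)
    ps = [d / total for d in dwells]
    clat = sum(p * c[0] for p, c in zip(ps, centroids))
    clon = sum(p * c[1] for p, c in zip(ps, centroids))
    return math.sqrt(sum(
        p * ref_haversine(c[0], c[1], clat, clon) ** 2
        for p, c in zip(ps, centroids)))


def ref_bouts(steps):
    """steps: list of per-minute counts (contiguous coverage).
    Returns list of (kind, length, total_steps)."""
    bouts = []
    cur = []
    for s in steps:
        if cur and (s > 0) != (cur[-1] > 0):
            bouts.append(cur)
            cur = []
        cur.append(s)
    if cur:
        bouts.append(cur)
    return [("active" if seg[0] > 0 else "sedentary", len(seg), sum(seg))
            for seg in bouts]


def ref_fitbit_minutes(steps):
    bouts = ref_bouts(steps)
    sed = [ln for k, ln, _ in bouts if k == "sedentary"]
    act = [(ln, st) for k, ln, st in bouts if k == "active"]
    out = {
        "max_steps_per_min": max(steps),
        "n_sedentary_bouts": len(sed),
        "n_active_bouts": len(act),
    }
    if sed:
        out["sedentary_bout_min_len"] = min(sed)
        out["sedentary_bout_max_len"] = max(sed)
        out["sedentary_bout_mean_len"] = statistics.fmean(sed)
    if act:
        out["active_bout_min_len"] = min(ln for ln, _ in act)
        out["active_bout_max_len"] = max(ln for ln, _ in act)
        out["active_bout_mean_len"] = statistics.fmean(ln for ln, _ in act)
        out["active_bout_max_steps"] = max(st for _, st in act)
        out["active_bout_mean_steps"] = statistics.fmean(st for _, st in act)
    return out


def ref_screen(events, monitored_minutes):
    """events: list of (minute_of_day, state)."""
    total = 0.0
    unlocks = 0
    open_t = None
    for t, state in events:
        if state == "unlock":
            unlocks += 1
            open_t = t
        elif state in ("lock", "off") and open_t is not None:
            total += t - open_t
            open_t = None
    return {"interaction_duration": total,
            "unlocks_per_min": unlocks / monitored_minutes}


def ref_apps(sessions, monitored_minutes):
    """sessions: list of (app_id, start_minute, end_minute), in time order."""
    return {
        "app_use_time": sum(e - s for _, s, e in sessions),
        "n_unique_apps": len({a for a, _, _ in sessions}),
        "n_app_changes": sum(1 for (a, _, _), (b, _, _) in
                             zip(sessions, sessions[1:]) if a != b),
        "apps_per_min": len(sessions) / monitored_minutes,
    }


def ref_comm(events):
    """events: list of (channel, direction, hash, duration_s)."""
    out = {"n_in_calls": 0, "dur_in_calls": 0.0, "n_out_calls": 0,
           "dur_out_calls": 0.0, "n_missed_calls": 0, "n_in_sms": 0,
           "n_out_sms": 0}
    counts = {}
    for ch, d, h, dur in events:
        counts[h] = counts.get(h, 0) + 1
        if ch == "call" and d == "incoming":
            out["n_in_calls"] += 1
            out["dur_in_calls"] += dur
        elif ch == "call" and d == "outgoing":
            out["n_out_calls"] += 1
            out["dur_out_calls"] += dur
        elif d == "missed":
            out["n_missed_calls"] += 1
        elif ch == "sms" and d == "incoming":
            out["n_in_sms"] += 1
        elif ch == "sms" and d == "outgoing":
            out["n_out_sms"] += 1
    out["n_unique_correspondents"] = len(counts)
    top = max(counts.values())
    out["most_frequent_contact"] = min(
        h for h, c in counts.items() if c == top)
    return out


def ref_pearson(xs, ys):
    n = len(xs)
    mx, my = statistics.fmean(xs), statistics.fmean(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs)
                    * sum((y - my) ** 2 for y in ys))
    return num / den


def ref_cfs_merit(rcf_list, rff_pairs):
    """Merit from explicit |r| lists: rcf per member, rff per unordered pair."""
    k = len(rcf_list)
    rcf = statistics.fmean(rcf_list)
    if k == 1:
        return rcf
    rff = statistics.fmean(rff_pairs)
    return k * rcf / math.sqrt(k + k * (k - 1) * rff)
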
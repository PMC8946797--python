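"""Naive re-evaluation of the response criteria, used as an independent
oracle against the package's incremental state machines.

Every comparison is recomputed from scratch at every scan with plain
loops and inline arithmetic over the raw lesion measurements — no code
is shared with the engines beyond the dataclasses holding the inputs.
"""

MM = 30.4375  # days per month
PD2, PR2 = 0.25, 0.50
PDV, PRV = 0.40, 0.65
T2V, T2A = 1.00, 0.25
WINDOW, GAP = 6.0, 3.0


def _months(a, b):
    return (b - a).total_seconds() / 86400.0 / MM


def _sum2d(scan):
    return sum(l.diam_longest * l.diam_perp for l in scan.lesions
               if l.diam_longest >= 10.0 and l.diam_perp >= 10.0)


def _vol(scan):
    return sum(l.ce_volume or 0.0 for l in scan.lesions)


def _meas2d(scan):
    return any(l.diam_longest >= 10.0 and l.diam_perp >= 10.0
               for l in scan.lesions)


def _new(scan):
    return any(l.is_new for l in scan.lesions)


def _new_measurable(scan):
    return any(l.is_new and (
        (l.diam_longest >= 10.0 and l.diam_perp >= 10.0)
        or (l.ce_volume or 0.0) >= 1.0
    ) for l in scan.lesions)


def _has_ce(scan):
    return any(l.diam_longest > 0 or (l.ce_volume or 0.0) > 0
               for l in scan.lesions)


def _t2(scan, volumetric):
    return scan.t2flair_volume if volumetric else scan.t2flair_area


def _t2_progressed(cur, ref, volumetric):
    if cur.t2flair_new_lesion:
        return True
    c, r = _t2(cur, volumetric), _t2(ref, volumetric)
    if c is None or r is None:
        return False
    f = T2V if volumetric else T2A
    if r <= 0:
        return c > 0
    return c >= (1.0 + f) * r


def naive_assess(tl, criterion):
    """Label sequence + event summary for one criterion, recomputed
    naively. Returns (labels, event, event_date, psp_confirmed)."""
    volumetric = criterion in ("Vol-RANO", "Vol-mRANO")
    t2mode = {"RANO": False, "iRANO": False, "Vol-RANO": True}.get(criterion)
    confirm = ("mrano" if criterion in ("mRANO", "Vol-mRANO")
               else "irano" if criterion == "iRANO" else None)
    post = next(i for i, s in enumerate(tl.scans) if s.is_post_op)
    scans = tl.scans[post:]
    metric = (_vol if volumetric else _sum2d)
    measurable = ((lambda s: _vol(s) >= 1.0) if volumetric else _meas2d)

    def raw_call(k, b):
        # recompute nadir from scratch over the prefix
        nad = min(metric(scans[i]) for i in range(b, k))
        pd = _new(scans[k]) or (measurable(scans[k])
                                and metric(scans[k]) >= (1.0 + (PDV if volumetric else PD2)) * nad)
        t2p = t2mode is not None and _t2_progressed(scans[k], scans[b], t2mode)
        if pd or t2p:
            return "PD"
        if measurable(scans[b]):
            if not _has_ce(scans[k]):
                return "CR"
            frac = PRV if volumetric else PR2
            if metric(scans[k]) <= (1.0 - frac) * metric(scans[b]):
                return "PR"
        return "SD"

    labels = []
    b = 0
    pending = None          # (kind, scan index, frozen baseline)
    post_psp = False
    event, event_date, psp = False, None, False
    for k in range(1, len(scans)):
        raw = raw_call(k, b)
        lab = None
        if event:
            lab = "PD"
        elif pending is not None and pending[0] == "PD":
            if confirm == "mrano":
                pk = pending[1]
                grown = measurable(scans[k]) and metric(scans[k]) >= (
                    1.0 + (PDV if volumetric else PD2)) * metric(scans[pk])
                if grown or _new_measurable(scans[k]):
                    event, event_date = True, scans[pk].scan_date
                    lab = "PD"
                else:
                    psp, lab, b, post_psp = True, "PsP_adjudicated", k, True
                pending = None
            else:  # irano
                pk, b0 = pending[1], pending[2]
                nad0 = min(metric(scans[i]) for i in range(b0, pk))
                ce = _new(scans[k]) or (measurable(scans[k])
                                        and metric(scans[k]) >= (1.0 + PD2) * nad0)
                met = ce or _t2_progressed(scans[k], scans[b0], False)
                if _months(scans[pk].scan_date, scans[k].scan_date) >= GAP:
                    if met:
                        event, event_date = True, scans[pk].scan_date
                        lab = "PD"
                    else:
                        psp, lab, b = True, "PsP_adjudicated", k
                    pending = None
                else:
                    lab = "preliminary_PD" if (met or raw == "PD") else raw
        elif pending is not None:
            if raw == "PD":
                lab = "pseudoresponse_adjudicated"
                pending = ("PD", k, b)
            else:
                lab = raw
                pending = None
        if lab is None:
            if raw == "PD":
                if confirm is None:
                    event, event_date, lab = True, scans[k].scan_date, "PD"
                elif confirm == "mrano":
                    if post_psp:
                        event, event_date, lab = True, scans[k].scan_date, "PD"
                    else:
                        lab, pending = "preliminary_PD", ("PD", k, b)
                else:
                    since = ((scans[k].scan_date - tl.immunotherapy_start
                              ).total_seconds() / 86400.0 / MM)
                    if 0.0 <= since <= WINDOW:
                        lab, pending = "preliminary_PD", ("PD", k, b)
                    else:
                        event, event_date, lab = True, scans[k].scan_date, "PD"
            elif raw in ("PR", "CR") and confirm == "mrano":
                lab, pending = "preliminary_PR_or_CR", ("PR", k, b)
            else:
                lab = raw
        labels.append(lab)
        if not event and pending is None:
            cur, ref = metric(scans[k]), metric(scans[b])
            if cur < ref:
                b = k
            elif cur == ref and t2mode is not None:
                tc, tr = _t2(scans[k], t2mode), _t2(scans[b], t2mode)
                if tc is not None and tr is not None and tc < tr:
                    b = k
    return labels, event, event_date, psp
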
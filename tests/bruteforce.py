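"""Independent brute-force scorer used as an oracle in tests.

Deliberately naive: works directly off the per-event spot *roles* recorded
in the log (never off the assignment object or the layout geometry the
production scorer uses), with plain loops and no shared code.
"""

REWARDED_ROLES = ("active_rewarded", "inactive_rewarded")


def _trials(log):
    trials = {}
    for ev in log.events:
        trials.setdefault(ev.trial_index, []).append(ev)
    ordered = [trials[k] for k in sorted(trials)]
    return [t for t in ordered if t[-1].rewarded]


def bf_first_choice_never_rewarded_rate(log, n_trials=100, include_first_trial=True):
    trials = _trials(log)[:n_trials]
    if not include_first_trial:
        trials = [t for t in trials if t[0].trial_index >= 2]
    assert trials, "undefined"
    hits = 0
    for t in trials:
        if t[0].spot_role == "never_rewarded":
            hits += 1
    return 100.0 * hits / len(trials)


def bf_move_pattern_rates(log, n_trials=100):
    trials = _trials(log)[:n_trials]
    assert len(trials) >= 2, "undefined"
    diag = adj = re_ = 0
    for k in range(1, len(trials)):
        prev_correct = trials[k - 1][-1].spot
        first = trials[k][0]
        if first.spot == prev_correct:
            re_ += 1
        elif first.spot_role in REWARDED_ROLES:
            diag += 1  # the only other spot on the rewarded diagonal
        else:
            adj += 1  # a never-rewarded spot, necessarily a neighbour
    n = diag + adj + re_
    return 100.0 * diag / n, 100.0 * adj / n, 100.0 * re_ / n


def bf_cumulative_diagonal_counts(log, n_choices=150):
    events = list(log.events)[:n_choices]
    series = []
    correct = error = 0
    for i in range(len(events)):
        if i > 0:
            a, b = events[i - 1], events[i]
            if a.spot != b.spot:
                if a.spot_role in REWARDED_ROLES and b.spot_role in REWARDED_ROLES:
                    correct += 1
                if a.spot_role == "never_rewarded" and b.spot_role == "never_rewarded":
                    error += 1
        series.append((correct, error))
    return series


def bf_never_rewarded_rate_blocks(log, block=5, n_trials=40):
    trials = _trials(log)[:n_trials]
    assert len(trials) >= block, "undefined"
    rates = []
    for start in range(0, (len(trials) // block) * block, block):
        pokes = [ev for t in trials[start : start + block] for ev in t]
        hits = sum(1 for ev in pokes if ev.spot_role == "never_rewarded")
        rates.append(100.0 * hits / len(pokes))
    return rates
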
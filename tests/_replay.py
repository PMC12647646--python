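"""Independent brute-force replay of the memory-bank insertion rules,
shared by the unit and acceptance suites."""

import numpy as np

from clamrfo.memory import DIVERSITY_DIST_FRAC, IMPROVE_FRAC, euclidean, relative_improvement


def replay_checker(events, capacity=15):
    """Independent brute-force replay of the bank rules.

    Verifies, for every accepted insertion: quality banks were either not
    full, freed a stale slot without degrading, or the candidate improved
    the worst stored fitness by >= 10%; the diversity bank acceptance
    respected the 50%-of-minimum-pairwise-distance rule; and no bank ever
    exceeded its capacity.
    """
    cap = capacity // 3
    short, long_, div = [], [], []  # (fitness, born) / positions

    def check_quality(bank, fitness, accepted, it, stale_ok):
        if len(bank) < cap:
            assert accepted
            return True
        worst = max(bank, key=lambda e: e[0])
        if stale_ok:
            stale = [e for e in bank if it - e[1] > 50]
            if stale and fitness < max(s[0] for s in stale):
                assert accepted
                bank.remove(max(stale, key=lambda e: e[0]))
                return True
        ok = relative_improvement(worst[0], fitness) >= IMPROVE_FRAC
        assert accepted == ok
        if ok:
            bank.remove(worst)
        return ok

    for it, pos, fit, rep in events:
        if not np.isfinite(fit):
            assert not rep.any
            continue
        if check_quality(short, fit, rep.short_term, it, stale_ok=True):
            short.append((fit, it))
        if check_quality(long_, fit, rep.long_term, it, stale_ok=False):
            long_.append((fit, it))
        if len(div) < 2:
            ok = all(euclidean(pos, q) > 0 for q in div)
            assert rep.diversity == ok
        else:
            dmin = min(euclidean(pos, q) for q in div)
            pmin = min(
                euclidean(div[i], div[j])
                for i in range(len(div))
                for j in range(i + 1, len(div))
            )
            ok = dmin > DIVERSITY_DIST_FRAC * pmin
            assert rep.diversity == ok
            if ok and len(div) >= cap:
                crowd = [min(euclidean(e, o) for o in div if o is not e) for e in div]
                div.pop(int(np.argmin(crowd)))
        if rep.diversity:
            div.append(pos.copy())
        assert len(short) <= cap and len(long_) <= cap and len(div) <= cap


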
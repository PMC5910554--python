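"""Aho-Corasick automaton for single-pass multi-pattern substring search.

One scan of a text reports every stored pattern occurring in it, in time
proportional to text length plus number of hits — the contract needed to
screen digested peptides against tens of thousands of database sequences
without an all-pairs loop.
"""

from __future__ import annotations

from collections import deque

__all__ = ["AhoCorasick"]


class AhoCorasick:
    """Immutable-after-build automaton over a set of string patterns."""

    def __init__(self, patterns):
        # goto: list of dict char -> state; output: pattern indices ending at state
        self.patterns = list(patterns)
        self._goto = [{}]
        self._out = [[]]
        for idx, pat in enumerate(self.patterns):
            if not pat:
                raise ValueError("empty pattern")
            state = 0
            for ch in pat:
                nxt = self._goto[state].get(ch)
                if nxt is None:
                    self._goto.append({})
                    self._out.append([])
                    nxt = len(self._goto) - 1
                    self._goto[state][ch] = nxt
                state = nxt
            self._out[state].append(idx)
        self._fail = [0] * len(self._goto)
        queue = deque()
        for state in self._goto[0].values():
            queue.append(state)
        while queue:
            state = queue.popleft()
            for ch, nxt in self._goto[state].items():
                queue.append(nxt)
                fall = self._fail[state]
                while fall and ch not in self._goto[fall]:
                    fall = self._fail[fall]
                self._fail[nxt] = self._goto[fall].get(ch, 0)
                if self._fail[nxt] == nxt:
                    self._fail[nxt] = 0
                self._out[nxt] = self._out[nxt] + self._out[self._fail[nxt]]

    def scan(self, text):
        """Yield (pattern_index, start) for every occurrence (0-based start)."""
        goto, fail, out = self._goto, self._fail, self._out
        patterns = self.patterns
        state = 0
        for pos, ch in enumerate(text):
            while state and ch not in goto[state]:
                state = fail[state]
            state = goto[state].get(ch, 0)
            for idx in out[state]:
                yield idx, pos - len(patterns[idx]) + 1
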
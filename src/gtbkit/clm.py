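"""Cyclic locking model: ordered parallel output and its timing planner.

Workers process tasks concurrently but may emit their result only after the
previous task's result has been written, so the sink is byte-identical to a
serial run regardless of thread count or per-task jitter.  The ordering is
enforced as a contract (write i may not start before write i-1 completed);
the analytic model below predicts the wall time of a ring of ``n`` threads
over ``k`` equal tasks:

    t_total = ceil(k/n)(t_o + t_p) + ((k-1) mod n) t_o
              + max((n-1) t_o - t_p, 0) (ceil(k/n) - 1) + k n t_eps

where t_p is per-task processing time, t_o per-task output time and t_eps
the thread-switch cost.  Parallelism pays off for
n <= ceil(t_p / t_o) + 1 threads.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass


@dataclass(frozen=True)
class CLMParams:
    """Planner inputs: k tasks, n threads, unit times (seconds)."""

    k: int
    n: int
    t_o: float
    t_p: float
    t_eps: float = 0.0

    def __post_init__(self):
        if self.k < 1 or self.n < 1:
            raise ValueError("need k >= 1 tasks and n >= 1 threads")
        if min(self.t_o, self.t_p, self.t_eps) < 0:
            raise ValueError("times must be non-negative")

    @classmethod
    def from_speeds(cls, S: float, k: int, n: int, v_o: float, v_p: float,
                    t_eps: float = 0.0) -> "CLMParams":
        """Derive unit times from a payload of S bytes and unit speeds."""
        return cls(k=k, n=n, t_o=S / (k * v_o), t_p=S / (k * v_p), t_eps=t_eps)


def total_time(p: CLMParams) -> float:
    """Predicted wall time of the lock ring (exact for equal task times)."""
    waves = math.ceil(p.k / p.n)
    return (waves * (p.t_o + p.t_p)
            + ((p.k - 1) % p.n) * p.t_o
            + max((p.n - 1) * p.t_o - p.t_p, 0.0) * (waves - 1)
            + p.k * p.n * p.t_eps)


def efficiency(p: CLMParams) -> float:
    """Serial work divided by predicted parallel wall time (E_n)."""
    return p.k * (p.t_o + p.t_p) / total_time(p)


def efficient_threads(t_o: float, t_p: float) -> set[int]:
    """Thread counts for which the ring stays efficient: {1..ceil(t_p/t_o)+1}.

    The set always reaches 2: overlapping one task's processing with the
    previous task's write never hurts, so ordered output costs nothing at
    two threads even for pure-output workloads.
    """
    if t_o <= 0:
        raise ValueError("t_o must be positive")
    return set(range(1, max(math.ceil(t_p / t_o) + 1, 2) + 1))


class OrderedExecutionError(RuntimeError):
    """A task failed; the in-order completed prefix was flushed first."""


def ordered_imap(tasks, process, n_threads: int = 1,
                 max_pending: int | None = None):
    """Lazily map ``process`` over ``tasks`` with ``n_threads``, yielding
    results strictly in task order.

    At most ``max_pending`` (default 2n) tasks are in flight, bounding the
    out-of-order buffer; workers stay alive across waves.
    """
    if n_threads <= 1:
        idx = -1
        try:
            for idx, t in enumerate(tasks):
                yield process(t)
        except Exception as exc:
            raise OrderedExecutionError(f"task {idx} failed: {exc}") from exc
        return

    # Result i is released only after i-1 was consumed — the cyclic lock.
    with ThreadPoolExecutor(max_workers=n_threads) as pool:
        window = max_pending or 2 * n_threads
        futures = {}
        it = enumerate(tasks)
        next_yield = 0
        exhausted = False
        try:
            while True:
                while not exhausted and len(futures) < window:
                    try:
                        i, t = next(it)
                    except StopIteration:
                        exhausted = True
                        break
                    futures[i] = pool.submit(process, t)
                if next_yield not in futures:
                    break
                yield futures.pop(next_yield).result()
                next_yield += 1
        except Exception as exc:
            # results are yielded strictly in order, so every task before
            # the failing one is already out; just abort the ring
            for fut in futures.values():
                fut.cancel()
            raise OrderedExecutionError(
                f"task {next_yield} failed: {exc}") from exc


def ordered_execute(tasks, process, sink, n_threads: int = 1,
                    max_pending: int | None = None) -> int:
    """Run ``process`` over ``tasks`` with ``n_threads``, writing results to
    ``sink`` strictly in task order.

    ``sink`` is either an append-only file-like object (``write``) or a
    callable invoked per result.  On a task failure the in-order prefix of
    completed results has already been written when the error propagates.
    Returns the number of results written.
    """
    write = sink.write if hasattr(sink, "write") else sink
    written = 0
    for res in ordered_imap(tasks, process, n_threads, max_pending):
        write(res)
        written += 1
    return written
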
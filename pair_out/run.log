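WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
WARNING pairedval.signal: band edge 14250 Hz is at or above 95% of Nyquist (15000 Hz); design checked stable
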
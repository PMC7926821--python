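year,deaths
2010,772
2011,738
2012,624
2013,653
2014,648
2015,554
2016,735
2017,807
2018,840
2019,904
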
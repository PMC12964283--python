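year,exponent,r_squared,label
2000,0.7773,0.6847,NAG1
2001,0.7913,0.7061,NAG1
2002,0.8244,0.7164,NAG1
2003,0.8395,0.7436,NAG1
2004,0.8501,0.7455,PAG1
2005,0.8622,0.7483,PAG1
2006,0.8742,0.7655,PAG1
2007,0.9004,0.7996,PAG1
2008,0.9054,0.8339,PAG1
2009,0.9358,0.8634,PAG1
2010,0.9395,0.9011,PAG1
2011,0.9512,0.9107,PAG1
2012,0.9662,0.9334,PAG1
2013,0.9747,0.9379,PAG1
2014,0.9649,0.9324,PAG1
2015,1.0527,0.9458,PAG2
2016,1.0524,0.9456,PAG2
2017,1.0604,0.9010,PAG2
2018,1.0572,0.9026,PAG2
2019,1.0541,0.9082,PAG2
2020,1.0410,0.9432,PAG2
2021,1.0453,0.9406,PAG2
2022,1.0319,0.9483,PAG2
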
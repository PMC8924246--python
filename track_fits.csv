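track_id,D,alpha,mobility_class,fit_lags,rss,ok
0,0.16690871339341304,0.8037340561401576,diffusive,10,0.03998275280183536,True
1,0.4179792860396307,1.0216760770353206,diffusive,10,0.017977639773048157,True
2,0.26181568278499595,0.8612052311875422,diffusive,10,0.024676582912404363,True
3,0.3994555629508793,0.9720521681644969,diffusive,10,0.020820985837007748,True
4,0.36362243313829995,1.031254884700034,diffusive,10,0.008965226477684957,True
5,0.3760195515465556,0.9650503814418646,diffusive,10,0.03311650027499038,True
6,0.49277432741308874,1.0515435438782457,diffusive,10,0.014347426766000336,True
7,0.4781472306772701,0.9869503240997585,diffusive,10,0.014355880099230152,True
8,0.34486581508869524,0.9425572773063975,diffusive,10,0.0007159732982114158,True
9,0.4664357415928159,0.9911634361117692,diffusive,10,0.029203388218449255,True
10,0.363014416855852,0.9181433112008688,diffusive,10,0.006873076175805879,True
11,0.13325151872071048,0.6954950106314064,diffusive,10,0.046493836321720224,True
12,0.3998657132453099,1.009116589166609,diffusive,10,0.026804016494238157,True
13,0.27910978600991565,0.8370872194856116,diffusive,10,0.022004626413587122,True
14,0.5395411266340345,1.0930800686267181,diffusive,10,0.01843544645275469,True
15,0.7586999378628104,1.272879199935666,diffusive,10,0.1222345608965375,True
16,0.21458455793101053,0.8371997816884192,diffusive,10,0.021901466480976284,True
17,0.5855585479007657,1.03312717003625,diffusive,10,0.024016553845808575,True
18,0.24994533421719536,0.8774318088474649,diffusive,10,0.024305367404273248,True
19,0.19830899560786241,0.797715861089218,diffusive,10,0.007143495115848306,True
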
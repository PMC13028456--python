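Base Points,"More than 2,000,000","1,000,000 to 2,000,000","500,000 to 1,000,000","300,000 to 500,000","100,000 to 300,000","50,000 to 100,000","30,000 to 50,000","10,000 to 30,000","5000 to 10,000",3000 to 5000,1000 to 3000,500 to 1000,100 to 500,10 to 100,1 to 10
50,104,208,260,260,403,1209,1430,6500,"13,130","14,040","27,560","30,030","56,680","66,560","120,250"
45,96,192,240,240,372,1116,1320,6000,"12,120","12,960","25,440","27,720","52,320","61,440","111,000"
40,88,176,220,220,341,1023,1210,5500,"11,110","11,880","23,320","25,410","47,960","56,320","101,750"
35,80,160,200,200,310,930,1100,5000,"10,100","10,800","21,200","23,100","43,600","51,200","92,500"
30,72,144,180,180,279,837,990,4500,9090,9720,"19,080","20,790","39,240","46,080","83,250"
25,64,128,160,160,248,744,880,4000,8080,8640,"16,960","18,480","34,880","40,960","74,000"
20,56,112,140,140,217,651,770,3500,7070,7560,"14,840","16,170","30,520","35,840","64,750"
15,48,96,120,120,186,558,660,3000,6060,6480,"12,720","13,860","26,160","30,720","55,500"
10,40,80,100,100,155,465,550,2500,5050,5400,"10,600","11,550","21,800","25,600","46,250"
5,32,64,80,80,124,372,440,2000,4040,4320,8480,9240,"17,440","20,480","37,000"
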